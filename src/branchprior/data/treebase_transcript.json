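{
  "description": "Synthetic recorded transcript of a TreeBASE title/abstract search for cytochrome-b synonyms; replays offline for tests and demonstrations. All studies, abstracts and matrices are fabricated.",
  "query": {
    "synonyms": [
      "cytb",
      "cyt_b"
    ],
    "min_taxa": 4,
    "max_taxa": 100
  },
  "studies": [
    {
      "study_id": "S1777",
      "title": "Phylogeography of alpine newts inferred from cytb and 16S sequences",
      "abstract": "Mitochondrial cyt_b and 16S data for intraspecific sampling of alpine newts.",
      "matrix_url": "transcript://S1777.nex"
    },
    {
      "study_id": "S2043",
      "title": "Brittle star population structure from mitochondrial DNA",
      "abstract": "We analyse cytb haplotypes across Southern Ocean brittle star populations.",
      "matrix_url": "transcript://S2043.nex"
    },
    {
      "study_id": "S3001",
      "title": "A three-sample cytb survey of torrent frogs",
      "abstract": "Pilot sequencing of cytochrome b in torrent frogs.",
      "matrix_url": "transcript://S3001.nex"
    },
    {
      "study_id": "S4002",
      "title": "Lost-archive study of shrew cyt_b variation",
      "abstract": "Matrix withdrawn; download link broken.",
      "matrix_url": "transcript://S4002.nex"
    }
  ],
  "matrices": {
    "transcript://S1777.nex": "#NEXUS\n[ synthetic matrix fashioned after a TreeBASE download; not real study data ]\n\nBEGIN TAXA;\n    DIMENSIONS NTAX=5;\n    TAXLABELS newt_1 newt_2 newt_3 newt_4 newt_5;\nEND;\n\nBEGIN CHARACTERS;\n    DIMENSIONS NTAX=5 NCHAR=20;\n    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n    newt_1  ACGT{A,C}GGTACACGTTAGGCA\n    newt_2  ACGTAGGT{A,G}CACGTTAGGCA\n    newt_3  ACTTAGGTAC{C,T}CGTTAGGCA\n    newt_4  AC-TAGGTACACGT{A,C,G,T}AGGCA\n    newt_5  ACGTAGGTACACGTTAGGCA\n    ;\nEND;\n\nBEGIN SETS;\n    CHARSET cytb = 1-12;\n    CHARSET 16S = 13-20;\nEND;\n\nBEGIN TREES;\n    TREE tree1 = ((newt_1:0.1,newt_2:0.2):0.05,(newt_3:0.15,newt_4:0.12):0.03,newt_5:0.2);\nEND;\n\nBEGIN NOTES;\n    TEXT TAXON=1 TEXT='voucher notes';\nEND;\n",
    "transcript://S2043.nex": "#NEXUS\n[ synthetic matrix fashioned after a TreeBASE download; not real study data ]\n\nBEGIN DATA;\n    DIMENSIONS NTAX=4 NCHAR=12;\n    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n    star_a  ACGTACGTACGT\n    star_b  ACGT{C,T}CGTACGT\n    star_c  ACCTACGTACGT\n    star_d  ACGTACGTACTT\n    ;\nEND;\n",
    "transcript://S3001.nex": "#NEXUS\n[ synthetic matrix fashioned after a TreeBASE download; not real study data ]\n\nBEGIN DATA;\n    DIMENSIONS NTAX=3 NCHAR=8;\n    FORMAT DATATYPE=DNA MISSING=? GAP=-;\n    MATRIX\n    frog_a  ACGTACGT\n    frog_b  ACCTACGT\n    frog_c  ACGTAAGT\n    ;\nEND;\n"
  },
  "manifest": {
    "raw_records": 5,
    "fetched": 4,
    "failed": 1,
    "after_taxon_filter": 3,
    "final": 2,
    "final_files": [
      "S1777_cytb.nex",
      "S2043_cytb.nex"
    ]
  }
}
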