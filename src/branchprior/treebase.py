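"""Find outside datasets in TreeBASE that resemble a focal dataset.

The workflow: search study titles and abstracts for user-supplied gene-name
synonyms, download each hit's Nexus character matrix, drop matrices whose
sequence count falls outside user bounds, deduplicate studies hit by more
than one synonym, and assign canonical file names
``<study_id>_<synonym>.nex`` (the synonym being the earliest in the user's
list among that study's hits).

Network access is behind a :class:`Transport` interface.  Tests and offline
runs use :class:`TranscriptTransport`, which replays a recorded JSON
transcript of searches and downloads; :class:`LiveTransport` talks to the
TreeBASE phylows API over HTTP.  The behavioral contracts (ordering,
filtering, dedup) are identical under either transport.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
import re
import time
import urllib.parse
import urllib.request
from concurrent.futures import ThreadPoolExecutor
from typing import Protocol

from .nexus_prep import count_taxa

__all__ = [
    "SearchQuery",
    "StudyRecord",
    "Transport",
    "TranscriptTransport",
    "LiveTransport",
    "search_studies",
    "fetch_matrices",
    "filter_by_taxa",
    "dedupe_and_name",
    "run_pipeline",
    "packaged_transcript_path",
]

logger = logging.getLogger(__name__)


class TransportError(RuntimeError):
    """A transport call failed after exhausting retries."""


def packaged_transcript_path() -> str:
    """Path to the synthetic demonstration transcript shipped with the package."""
    from importlib.resources import files

    return str(files("branchprior") / "data" / "treebase_transcript.json")


@dataclasses.dataclass(frozen=True)
class SearchQuery:
    """Gene synonyms (in priority order) plus sequence-count bounds."""

    synonyms: tuple[str, ...]
    min_taxa: int
    max_taxa: int
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if not self.synonyms:
            raise ValueError("at least one gene-name synonym required")
        if self.min_taxa < 1 or self.min_taxa > self.max_taxa:
            raise ValueError("need 1 <= min_taxa <= max_taxa")


@dataclasses.dataclass
class StudyRecord:
    """One TreeBASE study candidate flowing through the pipeline."""

    study_id: str
    matched_synonym: str
    matrix_url: str
    n_taxa: int | None = None
    local_path: str | None = None
    status: str = "pending"  # pending | fetched | failed | filtered_out | kept


class Transport(Protocol):
    """Answers title/abstract keyword searches and fetches matrix files."""

    def search(self, term: str) -> list[dict]:
        """Studies whose title or abstract matches ``term``.

        Each dict carries ``study_id``, ``title``, ``abstract``,
        ``matrix_url``.
        """
        ...

    def fetch(self, url: str) -> bytes: ...


_TOKEN_RE = re.compile(r"[A-Za-z0-9_]+")


def _token_match(term: str, text: str) -> bool:
    """Case-insensitive whole-token match (gene symbols are case-variable)."""
    t = term.lower()
    return any(tok.lower() == t for tok in _TOKEN_RE.findall(text))


class TranscriptTransport:
    """Replays a recorded search/download transcript from a JSON file.

    Transcript layout::

        {"studies":  [{"study_id", "title", "abstract", "matrix_url"}, ...],
         "matrices": {"<matrix_url>": "<nexus text>", ...},
         "manifest": {...}}        # expected stage counts, for verification

    Search is evaluated client-side with whole-token matching, mirroring
    what a title/abstract keyword search returns.
    """

    def __init__(self, source: str | os.PathLike | dict):
        if isinstance(source, dict):
            data = source
        else:
            with open(os.fspath(source)) as fh:
                data = json.load(fh)
        self.studies: list[dict] = data["studies"]
        self.matrices: dict[str, str] = data.get("matrices", {})
        self.manifest: dict = data.get("manifest", {})

    def search(self, term: str) -> list[dict]:
        return [
            s
            for s in self.studies
            if _token_match(term, s.get("title", "") + " " + s.get("abstract", ""))
        ]

    def fetch(self, url: str) -> bytes:
        if url not in self.matrices:
            raise TransportError(f"404: {url} not in transcript")
        return self.matrices[url].encode()


class LiveTransport:
    """TreeBASE phylows API over HTTP (stdlib urllib; no test depends on it)."""

    SEARCH_URL = (
        "https://treebase.org/treebase-web/search/studySearch.html"
        "?query=dcterms.title.ht:{term}+or+dcterms.abstract.ht:{term}&format=rss1"
    )

    def __init__(self, timeout: float = 30.0):
        self.timeout = timeout

    def search(self, term: str) -> list[dict]:
        url = self.SEARCH_URL.format(term=urllib.parse.quote(term))
        body = self.fetch(url).decode(errors="replace")
        out = []
        for sid in sorted(set(re.findall(r"TB2:S(\d+)", body))):
            out.append(
                {
                    "study_id": f"S{sid}",
                    "title": "",
                    "abstract": "",
                    "matrix_url": (
                        f"https://treebase.org/treebase-web/search/downloadAStudy.html"
                        f"?id={sid}&format=nexus"
                    ),
                }
            )
        return out

    def fetch(self, url: str) -> bytes:
        with urllib.request.urlopen(url, timeout=self.timeout) as resp:
            return resp.read()


def _with_retries(fn, *args, attempts: int = 3, backoff: float = 1.0):
    last: Exception | None = None
    for attempt in range(attempts):
        try:
            return fn(*args)
        except Exception as exc:  # noqa: BLE001 - transports raise arbitrary errors
            last = exc
            if attempt + 1 < attempts:
                time.sleep(backoff * 2**attempt)
    raise TransportError(f"failed after {attempts} attempts: {last}") from last


def search_studies(
    query: SearchQuery,
    transport: Transport,
    attempts: int = 3,
    backoff: float = 1.0,
) -> list[StudyRecord]:
    """One :class:`StudyRecord` per (study, synonym) hit, deterministically ordered.

    Order is (study_id, synonym position in the user's list); duplicate
    studies are resolved later by :func:`dedupe_and_name`.  A transport
    failure is retried, then reported listing the failed synonyms.
    """
    records: list[tuple[str, int, StudyRecord]] = []
    failed: list[str] = []
    for idx, synonym in enumerate(query.synonyms):
        try:
            hits = _with_retries(
                transport.search, synonym, attempts=attempts, backoff=backoff
            )
        except TransportError as exc:
            logger.error("search for %r failed: %s", synonym, exc)
            failed.append(synonym)
            continue
        for hit in hits:
            rec = StudyRecord(
                study_id=hit["study_id"],
                matched_synonym=synonym,
                matrix_url=hit["matrix_url"],
            )
            records.append((rec.study_id, idx, rec))
    if failed:
        raise TransportError(f"searches failed for synonyms: {', '.join(failed)}")
    records.sort(key=lambda t: (t[0], t[1]))
    logger.info("%d studies matched across %d synonyms", len(records), len(query.synonyms))
    return [r for _, _, r in records]


def fetch_matrices(
    records: list[StudyRecord],
    transport: Transport,
    out_dir: str | os.PathLike,
    max_workers: int = 4,
    attempts: int = 3,
    backoff: float = 1.0,
) -> list[StudyRecord]:
    """Download each record's Nexus matrix and fill in its sequence count.

    Downloads run on independent threads, but the final record list and
    file contents are independent of completion order (each record owns a
    distinct provisional file name).  A failed download marks its record
    ``failed``; the batch continues.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)

    def work(rec: StudyRecord) -> None:
        try:
            data = _with_retries(
                transport.fetch, rec.matrix_url, attempts=attempts, backoff=backoff
            )
        except TransportError as exc:
            logger.warning("download failed for %s: %s", rec.study_id, exc)
            rec.status = "failed"
            return
        path = os.path.join(out_dir, f"{rec.study_id}_{rec.matched_synonym}.nex")
        with open(path, "wb") as fh:
            fh.write(data)
        rec.local_path = path
        try:
            rec.n_taxa = count_taxa(path)
        except Exception as exc:
            logger.warning("cannot count taxa in %s: %s", path, exc)
            rec.status = "failed"
            return
        rec.status = "fetched"

    with ThreadPoolExecutor(max_workers=max_workers) as pool:
        list(pool.map(work, records))
    return records


def filter_by_taxa(records: list[StudyRecord], query: SearchQuery) -> list[StudyRecord]:
    """Keep records whose sequence count lies within the inclusive bounds.

    Out-of-range records have their downloaded files deleted and are logged
    with the reason.
    """
    kept = []
    for rec in records:
        if rec.status == "failed":
            continue
        if rec.n_taxa is None:
            raise ValueError(f"record {rec.study_id} has no taxon count; fetch first")
        if query.min_taxa <= rec.n_taxa <= query.max_taxa:
            kept.append(rec)
        else:
            logger.info(
                "dropping %s: %d sequences outside [%d, %d]",
                rec.study_id, rec.n_taxa, query.min_taxa, query.max_taxa,
            )
            rec.status = "filtered_out"
            if rec.local_path and os.path.exists(rec.local_path):
                os.remove(rec.local_path)
    return kept


def dedupe_and_name(
    records: list[StudyRecord], synonyms: tuple[str, ...] | None = None
) -> list[StudyRecord]:
    """One record per Study ID, named ``<study_id>_<synonym>.nex``.

    When one study was hit by several synonyms, the survivor keeps the
    earliest synonym in the user's list (``synonyms``; defaults to order of
    first appearance among the records).  Duplicate files are deleted.
    Idempotent, and independent of input record order.
    """
    if synonyms is None:
        seen: list[str] = []
        for rec in records:
            if rec.matched_synonym not in seen:
                seen.append(rec.matched_synonym)
        synonyms = tuple(seen)
    rank = {s: i for i, s in enumerate(synonyms)}
    by_study: dict[str, list[StudyRecord]] = {}
    for rec in records:
        by_study.setdefault(rec.study_id, []).append(rec)
    survivors = []
    for study_id in sorted(by_study):
        group = sorted(by_study[study_id], key=lambda r: rank.get(r.matched_synonym, len(rank)))
        winner, losers = group[0], group[1:]
        target = None
        if winner.local_path:
            target = os.path.join(
                os.path.dirname(winner.local_path),
                f"{winner.study_id}_{winner.matched_synonym}.nex",
            )
            if winner.local_path != target and os.path.exists(winner.local_path):
                os.replace(winner.local_path, target)
            winner.local_path = target
        else:
            winner.local_path = f"{winner.study_id}_{winner.matched_synonym}.nex"
        for loser in losers:
            logger.info("duplicate Study ID %s via %r dropped", study_id, loser.matched_synonym)
            if (
                loser.local_path
                and loser.local_path != target
                and os.path.exists(loser.local_path)
            ):
                os.remove(loser.local_path)
        winner.status = "kept"
        survivors.append(winner)
    return survivors


def run_pipeline(
    query: SearchQuery,
    transport: Transport,
    out_dir: str | os.PathLike,
    max_workers: int = 4,
    backoff: float = 1.0,
) -> dict:
    """Full search → fetch → filter → dedupe pipeline.

    Returns stage-by-stage record counts plus the final records, and writes
    a TSV manifest next to the downloaded files.
    """
    raw = search_studies(query, transport, backoff=backoff)
    fetched = fetch_matrices(raw, transport, out_dir, max_workers=max_workers, backoff=backoff)
    ok = [r for r in fetched if r.status == "fetched"]
    in_range = filter_by_taxa(fetched, query)
    final = dedupe_and_name(in_range, synonyms=query.synonyms)
    counts = {
        "raw_records": len(raw),
        "fetched": len(ok),
        "failed": sum(1 for r in fetched if r.status == "failed"),
        "after_taxon_filter": len(in_range),
        "final": len(final),
    }
    for stage, n in counts.items():
        logger.info("%s: %d records", stage, n)
    manifest_path = os.path.join(os.fspath(out_dir), "manifest.tsv")
    with open(manifest_path, "w") as fh:
        fh.write("study_id\tsynonym\tn_taxa\tstatus\tlocal_path\n")
        for rec in fetched:
            fh.write(
                f"{rec.study_id}\t{rec.matched_synonym}\t{rec.n_taxa}\t"
                f"{rec.status}\t{os.path.basename(rec.local_path) if rec.local_path else ''}\n"
            )
    return {"counts": counts, "records": final, "manifest": manifest_path}
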