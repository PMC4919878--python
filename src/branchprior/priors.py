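"""Render fitted branch-length distributions as prior declarations.

A converged :class:`~branchprior.fitting.FitResult` becomes a copy-paste
command for Bayesian phylogenetics software.  Supported targets:

* ``mrbayes`` — MrBayes 3.2 ``prset`` syntax.  For the compound Dirichlet
  this is ``unconstrained:gammadir(alpha_T, beta_T, alpha, c)`` with
  ``beta_T`` a gamma *rate*; for the exponential,
  ``unconstrained:exponential(rate)``.
* ``plain`` — a neutral ``key=value`` line for any other consumer.
"""

from __future__ import annotations

import dataclasses
import re

from .brldist import CompoundDirichletParams, ExpParams
from .fitting import FitResult

__all__ = ["PriorDeclaration", "render_prior", "parse_prior", "SUPPORTED_TARGETS"]

SUPPORTED_TARGETS = ("mrbayes", "plain")


@dataclasses.dataclass(frozen=True)
class PriorDeclaration:
    target: str
    distribution: str
    values: dict[str, float]
    precision: int
    command: str

    def __str__(self) -> str:
        return self.command


def render_prior(fit: FitResult, target: str = "mrbayes", precision: int = 2) -> PriorDeclaration:
    """Deterministic prior-declaration text for a converged fit.

    Raises ``ValueError`` for an unconverged fit or an unknown target tag.
    """
    if target not in SUPPORTED_TARGETS:
        raise ValueError(
            f"unknown target {target!r}; supported: {', '.join(SUPPORTED_TARGETS)}"
        )
    if not fit.converged:
        raise ValueError("refusing to render a prior from an unconverged fit")
    p = fit.params
    fmt = f"{{:.{precision}f}}"
    if isinstance(p, ExpParams):
        values = {"rate": p.rate}
        if target == "mrbayes":
            command = f"prset brlenspr=unconstrained:exponential({fmt.format(p.rate)});"
        else:
            command = f"distribution=exponential rate={fmt.format(p.rate)}"
    elif isinstance(p, CompoundDirichletParams):
        values = {"alpha_T": p.alpha_T, "beta_T": p.beta_T, "alpha": p.alpha, "c": p.c}
        nums = ",".join(fmt.format(v) for v in (p.alpha_T, p.beta_T, p.alpha, p.c))
        if target == "mrbayes":
            command = f"prset brlenspr=unconstrained:gammadir({nums});"
        else:
            command = "distribution=compound_dirichlet " + " ".join(
                f"{k}={fmt.format(v)}" for k, v in values.items()
            )
    else:  # pragma: no cover - FitResult guarantees one of the two
        raise TypeError(f"unknown parameter type {type(p).__name__}")
    return PriorDeclaration(
        target=target,
        distribution=fit.distribution,
        values=values,
        precision=precision,
        command=command,
    )


def parse_prior(command: str) -> dict[str, float]:
    """Recover the numeric parameters from a rendered prior string.

    Supports both output dialects; used to verify render/parse round trips.
    """
    m = re.search(r"unconstrained:exponential\(([\d.eE+-]+)\)", command)
    if m:
        return {"rate": float(m.group(1))}
    m = re.search(r"unconstrained:gammadir\(([^)]*)\)", command)
    if m:
        vals = [float(v) for v in m.group(1).split(",")]
        return dict(zip(("alpha_T", "beta_T", "alpha", "c"), vals))
    pairs = re.findall(r"(\w+)=([\d.eE+-]+)", command)
    if pairs:
        return {k: float(v) for k, v in pairs if k != "distribution"}
    raise ValueError(f"unrecognized prior declaration: {command!r}")
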