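"""Small-RNA-IP enrichment calling via a two-component Gaussian mixture.

Per-miRNA read counts from an IP library and its input library are CPM
normalized; the per-miRNA statistic is log2((ip + pseudo)/(input + pseudo)).
A two-component Gaussian mixture is fitted to the population of
log-enrichments by EM: the lower-mean component models background
(non-enriched) small RNAs, the higher-mean component the IP-enriched ones.

LOD(x) = log10( w1 phi(x; mu1, s1) / (w0 phi(x; mu0, s0)) ) — the posterior
log-odds of the enriched component; a miRNA is called enriched when
LOD > 0. Note the sign convention is the opposite of the proteomics stage
(there, LOD < 0 flags the signal class).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RipCountRecord",
    "MixtureModel",
    "EnrichmentResult",
    "read_rip_table",
    "filter_min_reads",
    "cpm_normalize",
    "log_enrichment",
    "fit_mixture",
    "call_enriched",
    "RipEnrichmentModel",
    "RipEnrichmentResults",
]

_VAR_FLOOR = 1e-6


@dataclass
class RipCountRecord:
    mirna_id: str
    input_reads: float
    ip_reads: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.input_reads < 0 or self.ip_reads < 0:
            raise ValueError(f"{self.mirna_id}: negative read counts")
        if not self.normalized:
            for v in (self.input_reads, self.ip_reads):
                if v != int(v):
                    raise ValueError(
                        f"{self.mirna_id}: raw reads must be integers"
                    )


@dataclass
class MixtureModel:
    """Two-component 1-D Gaussian mixture; component 0 is the lower-mean
    (background) component by convention."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    converged: bool
    loglik: float
    seed: int
    n_iter: int = 0
    loglik_trace: tuple[float, ...] = ()

    def component_density(self, x: np.ndarray, k: int) -> np.ndarray:
        return self.weights[k] * stats.norm.pdf(x, self.means[k], self.sds[k])


@dataclass
class EnrichmentResult:
    mirna_id: str
    log_enrichment: float
    lod: float
    enriched: bool


def read_rip_table(path) -> list[RipCountRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        RipCountRecord(str(r.mirna_id), float(r.input_reads), float(r.ip_reads))
        for r in df.itertuples(index=False)
    ]


def filter_min_reads(
    records: Sequence[RipCountRecord],
    min_reads: int = 20,
    arms: str = "both",
) -> list[RipCountRecord]:
    """Read floor against transcriptional noise. ``arms="both"`` (default)
    requires min_reads in IP and input; ``arms="ip"`` in the IP only."""
    if arms not in {"both", "ip"}:
        raise ValueError(f"arms must be 'both' or 'ip', got {arms!r}")
    if arms == "both":
        return [
            r
            for r in records
            if r.ip_reads >= min_reads and r.input_reads >= min_reads
        ]
    return [r for r in records if r.ip_reads >= min_reads]


def cpm_normalize(records: Sequence[RipCountRecord]) -> list[RipCountRecord]:
    """Counts-per-million by library arm."""
    ip_total = sum(r.ip_reads for r in records)
    input_total = sum(r.input_reads for r in records)
    if ip_total == 0 or input_total == 0:
        raise ValueError("zero library size; cannot CPM-normalize")
    return [
        RipCountRecord(
            r.mirna_id,
            r.input_reads / input_total * 1e6,
            r.ip_reads / ip_total * 1e6,
            normalized=True,
        )
        for r in records
    ]


def log_enrichment(
    records: Sequence[RipCountRecord], pseudo: float = 1.0
) -> pd.Series:
    """log2((ip_cpm + pseudo)/(input_cpm + pseudo)); records are CPM
    normalized first unless already flagged normalized."""
    if not records:
        raise ValueError("no records")
    if not all(r.normalized for r in records):
        records = cpm_normalize(records)
    vals = {
        r.mirna_id: math.log2((r.ip_reads + pseudo) / (r.input_reads + pseudo))
        for r in records
    }
    return pd.Series(vals, name="log_enrichment")


def fit_mixture(
    values: Sequence[float],
    k: int = 2,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> MixtureModel:
    """EM fit of a two-component Gaussian mixture.

    Initialization is deterministic (means at the 25%/75% quantiles, shared
    sd, equal weights); the seed is recorded for provenance. Components are
    relabelled at the end so component 0 has the lower mean.
    """
    if k != 2:
        raise ValueError("only k = 2 is supported")
    x = np.asarray(values, dtype=float)
    if x.size < 10:
        raise ValueError("need >= 10 values to fit the mixture")
    if np.ptp(x) == 0:
        raise ValueError("all values identical: degenerate variance")
    mu = np.array([np.quantile(x, 0.25), np.quantile(x, 0.75)])
    if mu[0] == mu[1]:
        mu = np.array([x.min(), x.max()])
    sd = np.full(2, max(x.std(), math.sqrt(_VAR_FLOOR)))
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    converged = False
    n_iter = 0
    trace: list[float] = []
    for n_iter in range(1, max_iter + 1):
        dens = w[None, :] * stats.norm.pdf(x[:, None], mu[None, :], sd[None, :])
        total = dens.sum(axis=1)
        total = np.maximum(total, 1e-300)
        ll = float(np.log(total).sum())
        trace.append(ll)
        resp = dens / total[:, None]
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, _VAR_FLOOR))
        if abs(ll - prev_ll) < tol:
            converged = True
            prev_ll = ll
            break
        prev_ll = ll
    order = np.argsort(mu)  # background = lower mean
    return MixtureModel(
        weights=(float(w[order[0]]), float(w[order[1]])),
        means=(float(mu[order[0]]), float(mu[order[1]])),
        sds=(float(sd[order[0]]), float(sd[order[1]])),
        converged=converged,
        loglik=prev_ll,
        seed=seed,
        n_iter=n_iter,
        loglik_trace=tuple(trace),
    )


def call_enriched(
    values: pd.Series | Sequence[float],
    model: MixtureModel,
    ids: Sequence[str] | None = None,
) -> list[EnrichmentResult]:
    """LOD call per miRNA: enriched iff the posterior odds favour the
    higher-mean component (LOD > 0)."""
    if not model.converged:
        raise ValueError("mixture model did not converge")
    if isinstance(values, pd.Series):
        ids = list(values.index)
        x = values.to_numpy(dtype=float)
    else:
        x = np.asarray(values, dtype=float)
        if ids is None:
            ids = [str(i) for i in range(x.size)]
    d0 = np.maximum(model.component_density(x, 0), 1e-300)
    d1 = np.maximum(model.component_density(x, 1), 1e-300)
    lod = np.log10(d1 / d0)
    if not np.all(np.isfinite(lod)):
        raise ValueError("non-finite LOD")
    return [
        EnrichmentResult(str(i), float(v), float(l), bool(l > 0))
        for i, v, l in zip(ids, x, lod)
    ]


class RipEnrichmentModel:
    """Mixture-based enrichment caller for one RNA-IP sample vs its input."""

    def __init__(
        self,
        records: Sequence[RipCountRecord],
        min_reads: int = 20,
        pseudo: float = 1.0,
        seed: int = 0,
        arms: str = "both",
    ):
        self.records = list(records)
        self.min_reads = min_reads
        self.pseudo = pseudo
        self.seed = seed
        self.arms = arms

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "RipEnrichmentModel":
        records = [
            RipCountRecord(str(r.mirna_id), float(r.input_reads), float(r.ip_reads))
            for r in df.itertuples(index=False)
        ]
        return cls(records, **kwargs)

    def fit(self) -> "RipEnrichmentResults":
        kept = filter_min_reads(self.records, self.min_reads, self.arms)
        values = log_enrichment(kept, self.pseudo)
        mixture = fit_mixture(values.to_numpy(), seed=self.seed)
        calls = call_enriched(values, mixture)
        return RipEnrichmentResults(self, mixture, calls)


class RipEnrichmentResults:
    def __init__(
        self,
        model: RipEnrichmentModel,
        mixture: MixtureModel,
        calls: list[EnrichmentResult],
    ):
        self.model = model
        self.mixture = mixture
        self.calls = calls

    @property
    def enriched_ids(self) -> set[str]:
        return {c.mirna_id for c in self.calls if c.enriched}

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([vars(c) for c in self.calls])

    def summary(self) -> str:
        m = self.mixture
        n_enr = len(self.enriched_ids)
        return "\n".join(
            [
                "RNA-IP enrichment (two-component Gaussian mixture)",
                "=" * 50,
                f"miRNAs passing the {self.model.min_reads}-read floor: "
                f"{len(self.calls)}",
                f"enriched (LOD > 0): {n_enr}",
                f"background: weight {m.weights[0]:.3f}, "
                f"mean {m.means[0]:+.3f}, sd {m.sds[0]:.3f}",
                f"enriched:   weight {m.weights[1]:.3f}, "
                f"mean {m.means[1]:+.3f}, sd {m.sds[1]:.3f}",
                f"EM: {'converged' if m.converged else 'NOT converged'} "
                f"in {m.n_iter} iterations, loglik {m.loglik:.2f}",
            ]
        )

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        x = np.array([c.log_enrichment for c in self.calls])
        grid = np.linspace(x.min() - 1, x.max() + 1, 400)
        ax.hist(x, bins=50, density=True, alpha=0.3, color="grey")
        ax.plot(grid, self.mixture.component_density(grid, 0), "b-", label="background")
        ax.plot(grid, self.mixture.component_density(grid, 1), "r-", label="enriched")
        ax.set_xlabel("log2 IP/input enrichment")
        ax.set_ylabel("density")
        ax.legend()
        return ax
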