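"""Per-patient differential methylation: a negative-binomial exact test.

Each patient is compared one-vs-group against the controls on the merged
region count matrix.  The model for region counts is NB with
``var = mu + phi * mu**2``; a common dispersion ``phi`` is estimated from
the control columns only (patient columns carry true effects, and a
single-sample patient "group" offers no within-group replication).

The exact test conditions on the total of the patient pseudo-count and
the summed control pseudo-counts.  Writing ``r = 1/phi``, the patient
count is NB(mu, r) and the control sum NB(n*mu, n*r); both share the same
success probability, so the conditional law of the patient count given
the total is beta-negative-binomial and free of ``mu``:

    P(y | T) ∝ C(y + r - 1, y) * C(T - y + n*r - 1, T - y)

The two-sided p-value sums the conditional probabilities of all splits no
more probable than the observed one — the count-data analogue of Fisher's
exact test.  At ``phi = 0`` the conditional law degenerates to
Binomial(T, 1/(n+1)).

Multiple testing is controlled per patient with Benjamini-Hochberg, and a
region is called aberrant when the adjusted p is at or below alpha
(inclusive), hypo- or hypermethylated by the sign of the log2 fold
change.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .regions import RegionCountMatrix

ALPHA = 0.05
PHI_FLOOR = 1e-4

HYPO = "hypo"
HYPER = "hyper"
NONE = "none"


@dataclass
class DispersionEstimate:
    phi: float
    per_region_phi: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.phi < PHI_FLOOR:
            raise ValueError(f"phi below the {PHI_FLOOR} floor")


def normalize_libraries(matrix: RegionCountMatrix) -> np.ndarray:
    """TMM-style effective library sizes.

    Scaling factors come from the trimmed mean (30% of log-ratios, 5% of
    abundances, each tail) of per-region log2 ratios against a reference
    sample (the one with the largest raw library), computed over regions
    nonzero in both samples.  Factors are rescaled to geometric mean 1;
    effective size = raw size x factor.
    """
    counts = matrix.counts.astype(float)
    lib = matrix.library_sizes.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples to normalize")
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("all-zero sample column")
    ref = int(np.argmax(lib))
    factors = np.ones(counts.shape[1])
    pr = counts[:, ref] / lib[ref]
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        ps = counts[:, s] / lib[s]
        ok = (counts[:, s] > 0) & (counts[:, ref] > 0)
        if not ok.any():
            continue
        m = np.log2(ps[ok] / pr[ok])
        a = 0.5 * np.log2(ps[ok] * pr[ok])
        lo_m, hi_m = np.quantile(m, [0.30, 0.70])
        lo_a, hi_a = np.quantile(a, [0.05, 0.95])
        keep = (m >= lo_m) & (m <= hi_m) & (a >= lo_a) & (a <= hi_a)
        if not keep.any():
            keep = np.ones_like(m, dtype=bool)
        factors[s] = 2.0 ** np.mean(m[keep])
    factors /= np.exp(np.mean(np.log(factors)))
    return lib * factors


def estimate_dispersion(
    matrix: RegionCountMatrix,
    control_ids: Sequence[str],
    effective_sizes: np.ndarray | None = None,
) -> DispersionEstimate:
    """Common NB dispersion from the control columns, by method of moments.

    Control counts are scaled to a common library size; per region,
    ``phi_i = max(0, (s^2 - mbar) / mbar^2)``; the common value is the
    median over regions with mean >= 10, floored at 1e-4.
    """
    idx = [matrix.samples.index(c) for c in control_ids]
    if len(idx) < 3:
        raise ValueError("need at least 3 controls to estimate dispersion")
    sizes = (matrix.library_sizes if effective_sizes is None
             else np.asarray(effective_sizes))
    sizes = sizes[idx].astype(float)
    y = matrix.counts[:, idx] * (sizes.mean() / sizes)[np.newaxis, :]
    mbar = y.mean(axis=1)
    s2 = y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_region = np.where(mbar > 0, np.maximum(0.0, (s2 - mbar) / mbar**2), 0.0)
    informative = per_region[mbar >= 10]
    phi = float(np.median(informative)) if informative.size else 0.0
    return DispersionEstimate(phi=max(phi, PHI_FLOOR), per_region_phi=per_region)


_GRID_CACHE: dict[tuple[float, int], tuple[np.ndarray, ...]] = {}


def _log_weight_grids(phi: float, n_controls: int, T: int
                      ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cached gammaln grids over integer counts, shared across regions."""
    key = (phi, n_controls)
    cached = _GRID_CACHE.get(key)
    if cached is None or cached[0].size < T + 1:
        size = max(T + 1, 1024)
        k = np.arange(size)
        r = 1.0 / phi
        cached = (
            gammaln(k + r),
            gammaln(k + n_controls * r),
            gammaln(k + 1.0),
        )
        _GRID_CACHE[key] = cached
    return cached


def _conditional_logpmf(T: int, n_controls: int, phi: float) -> np.ndarray:
    """log P(patient pseudo-count = y | total = T) for y = 0..T."""
    y = np.arange(T + 1)
    if phi < 1e-8:
        return stats.binom.logpmf(y, T, 1.0 / (n_controls + 1))
    g_r, g_nr, g_fact = _log_weight_grids(phi, n_controls, T)
    logw = g_r[y] + g_nr[T - y] - g_fact[y] - g_fact[T - y]
    return logw - logsumexp(logw)


def exact_nb_test(
    patient_count: float,
    control_counts: Sequence[float],
    phi: float,
    effective_sizes: Sequence[float],
) -> tuple[float, float]:
    """Two-sided conditional exact test of one patient against n controls.

    ``effective_sizes`` holds the patient's effective library size first,
    then the controls'.  Counts are rescaled to the mean effective size
    (pseudo-counts) before conditioning.  Returns (p_raw, log2fc) where
    log2fc = log2((patient + 0.5) / (control mean + 0.5)) on the
    normalized scale.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    control_counts = np.asarray(control_counts, dtype=float)
    sizes = np.asarray(effective_sizes, dtype=float)
    if sizes.size != control_counts.size + 1:
        raise ValueError("need one effective size per sample (patient first)")
    common = sizes.mean()
    pseudo_p = int(round(patient_count * common / sizes[0]))
    pseudo_c = np.round(control_counts * common / sizes[1:]).astype(int)
    n = control_counts.size
    S = int(pseudo_c.sum())
    T = pseudo_p + S
    log2fc = float(np.log2((pseudo_p + 0.5) / (S / n + 0.5)))
    if T == 0:
        return 1.0, 0.0
    logp = _conditional_logpmf(T, n, phi)
    obs = logp[pseudo_p]
    p = float(np.exp(logsumexp(logp[logp <= obs + 1e-9])))
    return min(p, 1.0), log2fc


def adjust_bh(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_patient(
    matrix: RegionCountMatrix,
    patient: str,
    control_ids: Sequence[str],
    phi: float | None = None,
    effective_sizes: np.ndarray | None = None,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Full one-vs-controls differential table for one patient.

    Returns a frame with chrom/start/end, sample, counts, log2fc, p_raw,
    p_adj and direction (hypo / hyper / none at ``alpha``, inclusive).
    """
    if effective_sizes is None:
        effective_sizes = normalize_libraries(matrix)
    if phi is None:
        phi = estimate_dispersion(matrix, control_ids, effective_sizes).phi
    pi = matrix.samples.index(patient)
    ci = [matrix.samples.index(c) for c in control_ids]
    sizes = np.concatenate([[effective_sizes[pi]], effective_sizes[ci]])
    rows = []
    for i, region in enumerate(matrix.regions):
        p_raw, lfc = exact_nb_test(
            matrix.counts[i, pi], matrix.counts[i, ci], phi, sizes
        )
        rows.append((region.chrom, region.start, region.end,
                     patient, int(matrix.counts[i, pi]), lfc, p_raw))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sample",
                                     "patient_count", "log2fc", "p_raw"])
    df["p_adj"] = adjust_bh(df["p_raw"].to_numpy())
    df["direction"] = call_aberrant(df["p_adj"].to_numpy(),
                                    df["log2fc"].to_numpy(), alpha)
    return df


def call_aberrant(p_adj: np.ndarray, log2fc: np.ndarray, alpha: float = ALPHA
                  ) -> np.ndarray:
    """Direction labels: hypo/hyper when p_adj <= alpha (inclusive),
    by the sign of the log2 fold change."""
    p_adj = np.asarray(p_adj, dtype=float)
    log2fc = np.asarray(log2fc, dtype=float)
    sig = p_adj <= alpha
    if np.any(sig & (log2fc == 0)):
        raise RuntimeError(
            "significant region with zero fold change — inconsistent input"
        )
    out = np.full(p_adj.shape, NONE, dtype=object)
    out[sig & (log2fc < 0)] = HYPO
    out[sig & (log2fc > 0)] = HYPER
    return out
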