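"""The weighted spectrum-peptide-protein (WSPP) quantification model.

The model treats an isobaric-label experiment as a three-level hierarchy.
Each identified spectrum contributes a log2 ratio ``x_s = log2(I_A/I_B)``
between the summed reporter intensities of the test and reference cohorts,
with a Poisson-like intensity-dependent variance

    v_s = k * (1/I_A + 1/I_B).

Spectrum ratios are averaged into peptide ratios with inverse-variance
weights; peptides are averaged into protein ratios with weights that add a
peptide-level variance component sigma_P^2; and proteins scatter about the
grand mean with an additional protein-level component sigma_Q^2.  The final
statistic is the standardized protein change

    Zq = (x_q - xbar) * sqrt(Wq),    Wq = 1 / (1/W_q_within + sigma_Q^2),

the mean-corrected log2 ratio expressed in units of standard deviation.
Under the null hypothesis (no abundance change) Zq is standard normal, so
|Zq| >= 2 corresponds to p < 0.05 and the whole Zq vector supports
threshold-free, proteome-wide category statistics downstream.

Variance components are estimated from the data: ``k`` by robust calibration
of within-peptide residuals, sigma_P^2 and sigma_Q^2 by a method-of-moments
root search.  Contaminant proteins (plasma proteins, epidermal cytokeratins)
can be excluded before grand-mean and sigma_Q^2 estimation so that the null
distribution of Zq stays normal; excluded proteins still receive a Zq for
transparency but are flagged and kept out of all downstream analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError, EmptyInputError, EstimationError
from .io import DesignConfig, ExclusionList, QuantTable

# median absolute deviation of a standard normal
_NORMAL_MAD = 0.6744897501960817

__all__ = [
    "SpectrumRatios",
    "VarianceComponents",
    "ComparisonResult",
    "compute_spectrum_ratios",
    "fit_spectrum_variance",
    "apply_spectrum_variance",
    "aggregate_peptides",
    "estimate_sigma2",
    "aggregate_proteins",
    "standardize",
    "run_wspp",
]


@dataclass
class SpectrumRatios:
    """Spectrum-level log2 ratios for one comparison.

    ``data`` columns: spectrum_id, peptide_key, protein_id, I_A, I_B, x_s,
    and (after variance fitting) v_s and w_s.  Rows are canonically sorted
    by spectrum_id so every downstream reduction is order-independent.
    """

    data: pd.DataFrame
    n_dropped: int
    comparison: tuple[str, str]


@dataclass
class VarianceComponents:
    """Estimated noise scales of the three model levels."""

    k: float
    sigma2_P: float
    sigma2_Q: float
    iterations: int = 1
    converged: bool = True

    def __post_init__(self) -> None:
        if not (self.k > 0 and self.sigma2_P >= 0 and self.sigma2_Q >= 0):
            raise EstimationError(
                f"invalid variance components: k={self.k}, "
                f"sigma2_P={self.sigma2_P}, sigma2_Q={self.sigma2_Q}"
            )


@dataclass
class ComparisonResult:
    """Protein-level output of one cohort comparison.

    ``proteins`` columns: protein_id, x_q, W_q_within, Wq, Xprime_q, Zq,
    n_peptides, n_spectra, excluded_flag.  ``gof`` holds normality
    diagnostics of the included Zq values (empirical mean/SD, KS statistic
    and p-value against N(0,1), and QQ-plot coordinates).
    """

    comparison: tuple[str, str]
    proteins: pd.DataFrame
    variance: VarianceComponents
    grand_mean: float
    gof: dict = field(default_factory=dict)
    n_dropped_spectra: int = 0

    @property
    def included(self) -> pd.DataFrame:
        return self.proteins[~self.proteins["excluded_flag"]]

    def zq_map(self, include_excluded: bool = False) -> dict[str, float]:
        df = self.proteins if include_excluded else self.included
        return dict(zip(df["protein_id"], df["Zq"]))


# ---------------------------------------------------------------------------
# spectrum level
# ---------------------------------------------------------------------------

def compute_spectrum_ratios(table: QuantTable, design: DesignConfig,
                            comparison: tuple[str, str]) -> SpectrumRatios:
    """Collapse cohort channels and form spectrum log2 ratios.

    Channel intensities of each cohort are summed (not log-averaged) before
    the ratio, keeping the Poisson-like noise model coherent.  Spectra with
    a zero total in either cohort are dropped and counted; no pseudocounts.
    """
    test, ref = comparison
    chans_a = design.channels_for(test)
    chans_b = design.channels_for(ref)
    for ch in (*chans_a, *chans_b):
        if ch not in table.data.columns:
            raise ConfigError(f"channel {ch!r} absent from the PSM table")

    df = table.data
    i_a = df[chans_a].to_numpy(dtype=float).sum(axis=1)
    i_b = df[chans_b].to_numpy(dtype=float).sum(axis=1)
    keep = (i_a > 0) & (i_b > 0)
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise EmptyInputError(
            f"comparison {test} vs {ref}: every spectrum has a zero-intensity side"
        )
    out = df.loc[keep, ["spectrum_id", "peptide_key", "protein_id"]].copy()
    out["I_A"] = i_a[keep]
    out["I_B"] = i_b[keep]
    out["x_s"] = np.log2(out["I_A"] / out["I_B"])
    out = out.sort_values("spectrum_id", kind="mergesort", ignore_index=True)
    return SpectrumRatios(out, n_dropped, (test, ref))


def fit_spectrum_variance(spectra: pd.DataFrame, min_spectra: int = 50) -> float:
    """Calibrate the spectrum noise scale ``k`` in ``v_s = k*(1/I_A + 1/I_B)``.

    Within-peptide residuals carry only spectrum noise, so ``k`` is set by
    matching the median absolute standardized residual

        r_s = (x_s - x_p) / sqrt(v_s * (1 - h_s)),   v_s = k u_s,

    to the standard-normal MAD (0.6745), over peptides with m >= 2 spectra;
    h_s = w_s / sum(w) is the leverage of the spectrum in its peptide mean,
    which reduces to the familiar m/(m-1) small-sample factor when the
    weights within a peptide are equal but stays exact when they are not.
    The median makes the calibration robust to outlier spectra.  Raises
    :class:`EstimationError` when fewer than ``min_spectra`` replicate
    spectra exist or the residuals are degenerate (advise a fixed-k override
    via :func:`run_wspp`).
    """
    u = 1.0 / spectra["I_A"].to_numpy() + 1.0 / spectra["I_B"].to_numpy()
    x = spectra["x_s"].to_numpy()
    work = pd.DataFrame({
        "key": spectra["protein_id"].astype(str) + "\x00" + spectra["peptide_key"].astype(str),
        "x": x, "invu": 1.0 / u,
    })
    work["wx"] = work["x"] * work["invu"]
    grp = work.groupby("key", sort=True)
    m = grp["x"].transform("size").to_numpy()
    wsum = grp["invu"].transform("sum").to_numpy()
    xp = grp["wx"].transform("sum").to_numpy() / wsum
    multi = m >= 2
    if int(multi.sum()) < min_spectra:
        raise EstimationError(
            f"only {int(multi.sum())} spectra in multi-spectrum peptides "
            f"(need >= {min_spectra}); supply a fixed k"
        )
    h = work["invu"].to_numpy() / wsum  # leverage in the peptide mean
    t = (x[multi] - xp[multi]) / np.sqrt(u[multi] * (1.0 - h[multi]))
    med = float(np.median(np.abs(t)))
    if med <= 0.0:
        raise EstimationError(
            "degenerate within-peptide residuals (all duplicates identical); "
            "supply a fixed k"
        )
    return (med / _NORMAL_MAD) ** 2


def apply_spectrum_variance(spectra: pd.DataFrame, k: float) -> pd.DataFrame:
    """Set ``v_s`` and ``w_s`` columns from a fitted (or fixed) ``k``."""
    if not k > 0:
        raise EstimationError(f"spectrum noise scale must be positive, got {k}")
    u = 1.0 / spectra["I_A"] + 1.0 / spectra["I_B"]
    spectra = spectra.copy()
    spectra["v_s"] = k * u
    spectra["w_s"] = 1.0 / spectra["v_s"]
    return spectra


# ---------------------------------------------------------------------------
# peptide and protein aggregation
# ---------------------------------------------------------------------------

def aggregate_peptides(spectra: pd.DataFrame) -> pd.DataFrame:
    """Inverse-variance average spectra into peptides.

    Returns one row per (protein_id, peptide_key) with the weighted mean
    ``x_p``, the within-weight ``W_p_within = sum(w_s)`` and ``n_spectra``.
    """
    if "w_s" not in spectra.columns:
        raise EstimationError("spectrum weights not set; fit or apply k first")
    work = spectra.assign(_wx=spectra["w_s"] * spectra["x_s"])
    agg = (work.groupby(["protein_id", "peptide_key"], sort=True)
               .agg(W_p_within=("w_s", "sum"), _wx=("_wx", "sum"),
                    n_spectra=("x_s", "size"))
               .reset_index())
    agg["x_p"] = agg["_wx"] / agg["W_p_within"]
    return agg[["protein_id", "peptide_key", "x_p", "W_p_within", "n_spectra"]]


def estimate_sigma2(child_values: Sequence[float], parent_values: Sequence[float],
                    within_weights: Sequence[float], n_eff: float | None = None,
                    min_pairs: int = 30) -> float:
    """Method-of-moments variance component from child-about-parent residuals.

    Solves, by monotone 1-D root search on sigma2 in [0, inf),

        sum_i (x_i - parent_i)^2 / (1/W_i + sigma2) = n_eff,

    where ``n_eff`` is the degrees-of-freedom-corrected pair count (defaults
    to ``len(pairs) - 1``; callers subtract one per fitted parent mean).
    The left side is strictly decreasing in sigma2, so the solution is
    unique; it is clipped to 0 when the equation has no positive root.
    """
    d2 = (np.asarray(child_values, float) - np.asarray(parent_values, float)) ** 2
    inv_w = 1.0 / np.asarray(within_weights, float)
    n = d2.size
    if n < min_pairs:
        raise EstimationError(f"need >= {min_pairs} child-parent pairs, got {n}")
    if n_eff is None:
        n_eff = n - 1
    if n_eff <= 0:
        raise EstimationError(f"non-positive effective pair count ({n_eff})")

    def excess(s2: float) -> float:
        return float(np.sum(d2 / (inv_w + s2))) - n_eff

    if excess(0.0) <= 0.0:
        return 0.0
    hi = max(float(np.mean(d2)), 1e-12)
    for _ in range(200):
        if excess(hi) < 0.0:
            break
        hi *= 2.0
    else:  # pragma: no cover - would need absurd inputs
        raise EstimationError("sigma2 bracketing failed to converge")
    return float(optimize.brentq(excess, 0.0, hi, xtol=1e-14, rtol=8.9e-16))


def aggregate_proteins(peptides: pd.DataFrame, sigma2_P: float) -> pd.DataFrame:
    """Average peptides into proteins with peptide weights
    ``w_p = 1/(1/W_p_within + sigma2_P)``.

    With sigma2_P = 0 this is pure inverse-variance averaging; as
    sigma2_P -> inf the weights equalize and ``x_q`` tends to the unweighted
    peptide mean.
    """
    if sigma2_P < 0:
        raise EstimationError("sigma2_P must be >= 0")
    w_p = 1.0 / (1.0 / peptides["W_p_within"] + sigma2_P)
    work = peptides.assign(w_p=w_p, _wx=w_p * peptides["x_p"])
    agg = (work.groupby("protein_id", sort=True)
               .agg(W_q_within=("w_p", "sum"), _wx=("_wx", "sum"),
                    n_peptides=("x_p", "size"), n_spectra=("n_spectra", "sum"))
               .reset_index())
    agg["x_q"] = agg["_wx"] / agg["W_q_within"]
    return agg[["protein_id", "x_q", "W_q_within", "n_peptides", "n_spectra"]]


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

def standardize(proteins: pd.DataFrame, sigma2_Q: float,
                exclusions: frozenset[str] | set[str] = frozenset(),
                comparison: tuple[str, str] = ("test", "reference"),
                variance: VarianceComponents | None = None,
                n_dropped_spectra: int = 0) -> ComparisonResult:
    """Mean-correct and standardize protein ratios into Zq.

    ``Wq = 1/(1/W_q_within + sigma2_Q)``; the grand mean is the Wq-weighted
    mean of NON-excluded proteins; ``Zq = (x_q - xbar)*sqrt(Wq)`` is computed
    for every protein (excluded ones are flagged and skipped downstream).
    Normality diagnostics (mean, SD, Kolmogorov-Smirnov vs N(0,1), QQ
    coordinates) are computed on the included Zq values.
    """
    if sigma2_Q < 0:
        raise EstimationError("sigma2_Q must be >= 0")
    df = proteins.copy()
    df["excluded_flag"] = df["protein_id"].isin(set(exclusions)).to_numpy()
    included = ~df["excluded_flag"].to_numpy()
    if not included.any():
        raise EmptyInputError("all proteins excluded; nothing to standardize")
    df["Wq"] = 1.0 / (1.0 / df["W_q_within"] + sigma2_Q)
    xbar = float(np.average(df.loc[included, "x_q"], weights=df.loc[included, "Wq"]))
    df["Xprime_q"] = df["x_q"] - xbar
    df["Zq"] = df["Xprime_q"] * np.sqrt(df["Wq"])

    z = np.sort(df.loc[included, "Zq"].to_numpy())
    n = z.size
    ks = stats.kstest(z, "norm")
    gof = {
        "n": int(n),
        "mean": float(np.mean(z)),
        "sd": float(np.std(z, ddof=1)) if n > 1 else float("nan"),
        "ks_stat": float(ks.statistic),
        "ks_pvalue": float(ks.pvalue),
        "qq": pd.DataFrame({
            "theoretical": stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n),
            "empirical": z,
        }),
    }
    if variance is None:
        variance = VarianceComponents(k=1.0, sigma2_P=0.0, sigma2_Q=sigma2_Q)
    cols = ["protein_id", "x_q", "W_q_within", "Wq", "Xprime_q", "Zq",
            "n_peptides", "n_spectra", "excluded_flag"]
    return ComparisonResult(comparison, df[cols], variance, xbar, gof,
                            n_dropped_spectra)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _sigma2_peptide_layer(peptides: pd.DataFrame, proteins: pd.DataFrame) -> float:
    merged = peptides.merge(proteins[["protein_id", "x_q"]], on="protein_id")
    n_eff = len(merged) - proteins["protein_id"].nunique()
    if n_eff <= 0:
        raise EstimationError(
            "no replicate peptides; supply a fixed sigma2_P to run_wspp"
        )
    return estimate_sigma2(merged["x_p"], merged["x_q"], merged["W_p_within"],
                           n_eff=n_eff)


def _sigma2_protein_layer(proteins: pd.DataFrame, exclusions: set[str],
                          sigma2_init: float = 0.0) -> float:
    incl = proteins[~proteins["protein_id"].isin(exclusions)]
    if incl.empty:
        raise EmptyInputError("all proteins excluded before sigma2_Q estimation")
    w_init = 1.0 / (1.0 / incl["W_q_within"] + sigma2_init)
    xbar = float(np.average(incl["x_q"], weights=w_init))
    return estimate_sigma2(incl["x_q"], np.full(len(incl), xbar),
                           incl["W_q_within"], n_eff=len(incl) - 1)


def run_wspp(table: QuantTable, design: DesignConfig, comparison: tuple[str, str],
             exclusions: ExclusionList | set[str] | None = None, *,
             k: float | None = None, sigma2_P: float | None = None,
             sigma2_Q: float | None = None) -> ComparisonResult:
    """Run the full WSPP cascade for one comparison.

    Deterministic composition: ratios -> fit k -> peptides -> sigma_P^2 ->
    proteins -> sigma_Q^2 -> standardize, with one outer re-estimation pass
    (the variance components are re-derived once from the improved protein
    means) and then fixed.  Keyword overrides pin any noise parameter, e.g.
    for tiny fixtures where replicate-based estimation is impossible.
    """
    if isinstance(exclusions, ExclusionList):
        excl = set(exclusions.accessions)
    else:
        excl = set(exclusions) if exclusions else set()

    ratios = compute_spectrum_ratios(table, design, comparison)
    k_hat = fit_spectrum_variance(ratios.data) if k is None else float(k)
    spectra = apply_spectrum_variance(ratios.data, k_hat)
    peptides = aggregate_peptides(spectra)

    prot0 = aggregate_proteins(peptides, 0.0)
    s2p = _sigma2_peptide_layer(peptides, prot0) if sigma2_P is None else float(sigma2_P)
    prot1 = aggregate_proteins(peptides, s2p)
    s2q = _sigma2_protein_layer(prot1, excl) if sigma2_Q is None else float(sigma2_Q)

    # one outer re-estimation pass: sharpen parents, then freeze
    iterations = 1
    if sigma2_P is None:
        s2p = _sigma2_peptide_layer(peptides, prot1)
        iterations = 2
    prot2 = aggregate_proteins(peptides, s2p)
    if sigma2_Q is None:
        s2q = _sigma2_protein_layer(prot2, excl, sigma2_init=s2q)

    vc = VarianceComponents(k=k_hat, sigma2_P=s2p, sigma2_Q=s2q,
                            iterations=iterations, converged=True)
    return standardize(prot2, s2q, excl, comparison, vc, ratios.n_dropped)
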