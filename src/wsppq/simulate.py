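"""Synthetic isobaric-labelling data with known ground truth.

The generator emulates an 8-channel experiment in which four cohorts own
two reporter channels each (two pooled groups split by age/disease/gender
style factors), at the PSM level:

* every protein gets a per-cohort log2 deviation ~ N(0, sigma_Q^2 / 2), so
  any cohort contrast has variance sigma_Q^2;
* every peptide adds a per-cohort deviation ~ N(0, sigma_P^2 / 2);
* every spectrum draws a lognormal base intensity, splits it over the
  channels, and perturbs each channel in log2 space with variance
  k_spec / I_channel — by the delta method the resulting log2 cohort ratio
  has variance k_spec * (1/I_A + 1/I_B), exactly the spectrum-noise law
  the quantification model assumes, for any channel balance;
* a minority of proteins receive a planted log2 shift (the true DAPs), a
  set of planted categories receive a coherent member shift with a random
  sign per category, and contaminant proteins (plasma/keratin stand-ins)
  receive a large common offset and appear on the exclusion list.

Generation is a pure function of the configuration (which embeds the
seed); the truth ledger covers every protein and category.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CategoryDB, DesignConfig, ExclusionList, QuantTable

__all__ = ["SimConfig", "SyntheticTruth", "SyntheticDataset", "generate",
           "make_fixture", "FIXTURE_NAMES"]

_DEFAULT_CHANNELS = ["113", "114", "115", "116", "117", "118", "119", "121"]
_DEFAULT_CHANNEL_MAP = {
    "113": "G1", "114": "G1", "115": "G2", "116": "G2",
    "117": "G3", "118": "G3", "119": "G4", "121": "G4",
}
_DEFAULT_COMPARISONS = [("G2", "G1"), ("G3", "G1"), ("G4", "G3")]


@dataclass
class SimConfig:
    """Generator settings; defaults mirror the emulated study design.

    ``sigma_P``/``sigma_Q`` are log2-scale standard deviations of the
    peptide and protein variance components; ``k_spec`` the spectrum noise
    scale of ``v_s = k*(1/I_A + 1/I_B)``.  Planted DAP and category shifts
    (``delta_dap``, ``delta_category``, log2 units) are applied to
    ``shift_cohort`` and never overlap on the same protein, so power and
    FDR attributions stay unambiguous.
    """

    n_proteins: int = 2000
    mean_peptides_per_protein: float = 3.0   # 1 + Poisson(mean - 1)
    mean_spectra_per_peptide: float = 2.0    # 1 + Poisson(mean - 1)
    channels: list[str] = field(default_factory=lambda: list(_DEFAULT_CHANNELS))
    channel_map: dict[str, str] = field(
        default_factory=lambda: dict(_DEFAULT_CHANNEL_MAP))
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [tuple(c) for c in _DEFAULT_COMPARISONS])
    base_log2_intensity_loc: float = 18.0
    base_log2_intensity_scale: float = 1.5
    k_spec: float = 400.0
    sigma_P: float = 0.15
    sigma_Q: float = 0.25
    frac_dap: float = 0.0
    delta_dap: float = 0.75
    shift_cohort: str = "G2"
    n_null_categories: int = 300
    n_planted_categories: int = 30
    category_size: int = 20
    delta_category: float = 0.2
    frac_contaminant: float = 0.0
    contaminant_offset: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frac_dap", "frac_contaminant"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("k_spec", "base_log2_intensity_scale"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.sigma_P < 0 or self.sigma_Q < 0:
            raise ConfigError("sigma_P and sigma_Q must be >= 0")
        if self.shift_cohort not in self.channel_map.values():
            raise ConfigError(f"shift_cohort {self.shift_cohort!r} not a cohort")

    def design(self) -> DesignConfig:
        return DesignConfig(channel_map=dict(self.channel_map),
                            comparisons=list(self.comparisons), seed=self.seed)


@dataclass
class SyntheticTruth:
    """Ground truth for every generated protein and category.

    ``protein_effects`` has one row per protein and one column per
    comparison label holding the realized true log2 effect (random cohort
    deviation plus any planted shift or contaminant offset).
    """

    protein_effects: pd.DataFrame
    contaminants: set[str]
    dap_proteins: dict[str, float]          # id -> signed planted shift
    planted_categories: dict[str, str]      # id -> "up" | "down"
    config: SimConfig


@dataclass
class SyntheticDataset:
    table: QuantTable
    categories: CategoryDB
    exclusions: ExclusionList
    truth: SyntheticTruth
    design: DesignConfig
    expected: dict | None = None


def generate(config: SimConfig) -> SyntheticDataset:
    """Draw one synthetic experiment; pure function of ``config`` (seed)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    cohorts = list(dict.fromkeys(config.channel_map.values()))
    cohort_col = {c: i for i, c in enumerate(cohorts)}
    shift_col = cohort_col[config.shift_cohort]

    # --- protein layer ----------------------------------------------------
    n_con = int(round(config.frac_contaminant * n))
    con_idx = rng.choice(n, size=n_con, replace=False) if n_con else np.array([], int)
    is_con = np.zeros(n, bool)
    is_con[con_idx] = True
    ids = np.array([f"CON{i:05d}" if is_con[i] else f"P{i:05d}" for i in range(n)])

    d_prot = rng.normal(0.0, config.sigma_Q / np.sqrt(2.0), size=(n, len(cohorts)))

    eligible = np.flatnonzero(~is_con)
    n_dap = int(round(config.frac_dap * eligible.size))
    dap_idx = rng.choice(eligible, size=n_dap, replace=False) if n_dap else np.array([], int)
    dap_sign = rng.choice([-1.0, 1.0], size=n_dap)
    d_prot[dap_idx, shift_col] += dap_sign * config.delta_dap

    pool = np.setdiff1d(eligible, dap_idx)
    need = config.n_planted_categories * config.category_size
    if need > pool.size:
        raise ConfigError(
            f"planted categories need {need} proteins, only {pool.size} available")
    planted_members = rng.choice(pool, size=need, replace=False)
    planted_members = planted_members.reshape(config.n_planted_categories,
                                              config.category_size)
    cat_sign = rng.choice([-1.0, 1.0], size=config.n_planted_categories)
    for row, s in zip(planted_members, cat_sign):
        d_prot[row, shift_col] += s * config.delta_category

    null_pool = np.setdiff1d(pool, planted_members.ravel())
    if config.n_null_categories and null_pool.size < config.category_size:
        raise ConfigError("not enough null proteins for null categories")

    d_prot[con_idx, shift_col] += config.contaminant_offset

    # --- categories -------------------------------------------------------
    categories: dict[str, tuple[str, frozenset[str]]] = {}
    planted_dirs: dict[str, str] = {}
    for j in range(config.n_planted_categories):
        cid = f"CAT{j + 1:04d}"
        categories[cid] = (f"synthetic category {j + 1}",
                           frozenset(ids[planted_members[j]]))
        planted_dirs[cid] = "up" if cat_sign[j] > 0 else "down"
    for j in range(config.n_null_categories):
        cid = f"CAT{config.n_planted_categories + j + 1:04d}"
        members = rng.choice(null_pool, size=config.category_size, replace=False)
        categories[cid] = (
            f"synthetic category {config.n_planted_categories + j + 1}",
            frozenset(ids[members]))

    # --- peptide and spectrum layers --------------------------------------
    n_pep = 1 + rng.poisson(max(config.mean_peptides_per_protein - 1, 0.0), n)
    pep_prot = np.repeat(np.arange(n), n_pep)             # protein index per peptide
    total_pep = pep_prot.size
    pep_within = np.concatenate([np.arange(k) for k in n_pep])
    d_pep = rng.normal(0.0, config.sigma_P / np.sqrt(2.0),
                       size=(total_pep, len(cohorts)))

    n_spec = 1 + rng.poisson(max(config.mean_spectra_per_peptide - 1, 0.0), total_pep)
    spec_pep = np.repeat(np.arange(total_pep), n_spec)    # peptide index per spectrum
    total_spec = spec_pep.size
    spec_prot = pep_prot[spec_pep]

    base = rng.normal(config.base_log2_intensity_loc,
                      config.base_log2_intensity_scale, size=total_spec)
    n_ch = len(config.channels)
    ch_cols = np.array([cohort_col[config.channel_map[ch]] for ch in config.channels])
    effect = d_prot[spec_prot][:, ch_cols] + d_pep[spec_pep][:, ch_cols]
    clean_log2 = base[:, None] - np.log2(n_ch) + effect
    i_clean = np.exp2(clean_log2)
    eps = rng.normal(0.0, 1.0, size=i_clean.shape) * np.sqrt(config.k_spec / i_clean)
    intensities = i_clean * np.exp2(eps)

    df = pd.DataFrame({
        "spectrum_id": [f"sp{i:07d}" for i in range(total_spec)],
        "peptide_key": [f"{ids[pep_prot[p]]}_p{pep_within[p] + 1}/2"
                        for p in spec_pep],
        "protein_id": ids[spec_prot],
    })
    for c, ch in enumerate(config.channels):
        df[ch] = intensities[:, c]
    table = QuantTable(df, list(config.channels))

    # --- truth ledger ------------------------------------------------------
    design = config.design()
    effects = {"protein_id": ids}
    for test, ref in design.comparisons:
        effects[f"{test}_vs_{ref}"] = (d_prot[:, cohort_col[test]]
                                       - d_prot[:, cohort_col[ref]])
    truth = SyntheticTruth(
        protein_effects=pd.DataFrame(effects),
        contaminants=set(ids[con_idx]),
        dap_proteins={ids[i]: float(s * config.delta_dap)
                      for i, s in zip(dap_idx, dap_sign)},
        planted_categories=planted_dirs,
        config=config,
    )
    exclusions = ExclusionList(set(ids[con_idx]), label="contaminant")
    return SyntheticDataset(table, CategoryDB(categories), exclusions,
                            truth, design)


# ---------------------------------------------------------------------------
# fixture registry
# ---------------------------------------------------------------------------

FIXTURE_NAMES = ("tiny_3x3", "null_medium", "planted_categories", "contaminated")


def _tiny_3x3() -> SyntheticDataset:
    """3 proteins x 3 peptides x 1 spectrum with hand-computable results.

    Reference channels (G1) carry 1000 each; G2 channels are scaled by
    2**e so every spectrum ratio is exactly e.  With a fixed k = 2000 and
    sigma_P = sigma_Q = 0 the exact weighted means and Zq are tabulated in
    ``expected`` (worked out by hand from the weight formulas).
    """
    rows = []
    spectra = [("P1", 1, 1.0), ("P1", 2, 1.0), ("P1", 3, 1.0),
               ("P2", 1, 0.0), ("P2", 2, 0.0), ("P2", 3, 0.0),
               ("P3", 1, -1.0), ("P3", 2, 0.0), ("P3", 3, 1.0)]
    for i, (prot, pep, e) in enumerate(spectra):
        row = {"spectrum_id": f"sp{i:03d}",
               "peptide_key": f"{prot}_p{pep}/2", "protein_id": prot}
        for ch in _DEFAULT_CHANNELS:
            cohort = _DEFAULT_CHANNEL_MAP[ch]
            row[ch] = 1000.0 * 2.0 ** e if cohort == "G2" else 1000.0
        rows.append(row)
    table = QuantTable(pd.DataFrame(rows), list(_DEFAULT_CHANNELS))
    design = DesignConfig(channel_map=dict(_DEFAULT_CHANNEL_MAP),
                          comparisons=[("G2", "G1")])
    xbar = 7.0 / 15.0
    expected = {
        "k": 2000.0, "sigma2_P": 0.0, "sigma2_Q": 0.0,
        "x_q": {"P1": 1.0, "P2": 0.0, "P3": 2.0 / 9.0},
        "W_q_within": {"P1": 2.0, "P2": 1.5, "P3": 1.5},
        "grand_mean": xbar,
        "Zq": {"P1": (1.0 - xbar) * np.sqrt(2.0),
               "P2": (0.0 - xbar) * np.sqrt(1.5),
               "P3": (2.0 / 9.0 - xbar) * np.sqrt(1.5)},
    }
    return SyntheticDataset(table, CategoryDB({}), ExclusionList(set(), "none"),
                            truth=None, design=design, expected=expected)


def make_fixture(name: str, seed: int = 0) -> SyntheticDataset:
    """Deterministic datasets used across the test suite.

    ``tiny_3x3``          hand-computed weighted means and Zq;
    ``null_medium``       2000 proteins, no planted effects;
    ``planted_categories`` 300 null + 30 planted categories (size 20,
                          coherent member shift 0.8 * sigma_Q);
    ``contaminated``      1000 proteins, 5% contaminants with a +2 log2
                          common offset and a matching exclusion list.
    """
    if name == "tiny_3x3":
        return _tiny_3x3()
    if name == "null_medium":
        cfg = SimConfig(n_proteins=2000, frac_dap=0.0, n_planted_categories=0,
                        n_null_categories=100, frac_contaminant=0.0, seed=seed)
    elif name == "planted_categories":
        cfg = SimConfig(n_proteins=2000, frac_dap=0.0, n_null_categories=300,
                        n_planted_categories=30, category_size=20,
                        delta_category=0.8 * 0.25, frac_contaminant=0.0,
                        seed=seed)
    elif name == "contaminated":
        cfg = SimConfig(n_proteins=1000, frac_dap=0.0, n_planted_categories=0,
                        n_null_categories=0, frac_contaminant=0.05,
                        contaminant_offset=2.0, seed=seed)
    else:
        raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    return generate(cfg)
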