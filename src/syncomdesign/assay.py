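"""Degradation-assay arithmetic: removal percentages, stoichiometric yields,
kinetic fits, and community-stability indices.

All quantities mirror how biodegradation assays are reported in practice:
percent removal relative to the initial concentration, fold improvement of a
consortium over its best monoculture member, theoretical element yields from
complete mineralization stoichiometry, first-order rate constants from
log-linear fits, and alpha/beta-diversity summaries of 16S relative-abundance
tables. Percentages are rounded to one decimal and fold ratios to two, the
conventional reporting precision; raw (unrounded) values are always returned
alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import braycurtis
from skbio.diversity import alpha as _skbio_alpha

__all__ = [
    "AssaySeries",
    "StoichiometrySpec",
    "AbundanceTable",
    "percent_removal",
    "fold_improvement",
    "theoretical_element_yield",
    "molar_element_yield",
    "percent_of_theoretical",
    "relative_change",
    "first_order_fit",
    "linear_window_fit",
    "diversity_indices",
    "community_stability_index",
    "convert_concentration",
    "mass_to_molar",
    "molar_to_mass",
]

#: Sentinel returned for a community-stability index whose coefficient of
#: variation is degenerate (zero mean or zero spread of dissimilarities).
CSI_SENTINEL = 1e6


@dataclass
class AssaySeries:
    """Time-resolved concentration (or abundance) measurements.

    Attributes
    ----------
    times : array of float
        Sampling times in days, strictly increasing.
    mean : array of float
        Mean concentration per time point (units carried in ``unit``).
    sd : array of float
        Replicate standard deviation per time point.
    n_reps : int
        Number of biological replicates behind each mean.
    unit : str
        Concentration unit label, e.g. ``"mg/L"`` or ``"uM"``.
    replicates : array or None
        Optional full replicate matrix, shape (n_times, n_reps).
    """

    times: np.ndarray
    mean: np.ndarray
    sd: np.ndarray
    n_reps: int = 1
    unit: str = "mg/L"
    replicates: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.mean.shape:
            raise ValueError("times and mean must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.mean < 0):
            raise ValueError("concentrations must be nonnegative")


@dataclass(frozen=True)
class StoichiometrySpec:
    """Element-release stoichiometry of one compound.

    e.g. atrazine (C8H14ClN5, M = 215.68 g/mol) carries 5 nitrogen atoms of
    atomic mass 14.007 g/mol, so complete mineralization of 1 mg/L releases
    5 * 14.007 / 215.68 mg N/L.
    """

    compound_molar_mass: float
    atoms_of_element: int
    element_molar_mass: float

    def __post_init__(self) -> None:
        if self.compound_molar_mass <= 0 or self.element_molar_mass <= 0:
            raise ValueError("molar masses must be positive")
        if self.atoms_of_element <= 0:
            raise ValueError("atoms_of_element must be positive")


@dataclass
class AbundanceTable:
    """Relative-abundance trajectories: rows = time points, cols = strains."""

    times: np.ndarray
    abundances: np.ndarray  # (n_times, n_strains), rows sum to 1
    strain_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim != 2:
            raise ValueError("abundances must be 2-D (time x strain)")
        if self.times.shape[0] != self.abundances.shape[0]:
            raise ValueError("times and abundance rows must align")
        sums = self.abundances.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("each time point's abundances must sum to 1 (+/- 1e-6)")


# ---------------------------------------------------------------------------
# ratios and percentages


def percent_removal(c0: float, ct: float) -> dict:
    """Percent of the initial concentration removed by time t.

    Returns ``{"percent": one-decimal value, "raw": unrounded}``.
    """
    if c0 <= 0:
        raise ValueError("initial concentration must be positive")
    if ct < 0:
        raise ValueError("final concentration must be nonnegative")
    raw = 100.0 * (c0 - ct) / c0
    return {"percent": round(raw, 1), "raw": raw}


def fold_improvement(consortium_pct: float, best_individual_pct: float) -> dict:
    """Ratio of consortium performance to the best monoculture performance."""
    if best_individual_pct <= 0:
        raise ValueError("best individual performance must be positive")
    raw = consortium_pct / best_individual_pct
    return {"fold": round(raw, 2), "raw": raw}


def theoretical_element_yield(concentration: float, spec: StoichiometrySpec) -> float:
    """Element mass released per volume by complete mineralization.

    ``concentration`` is the compound's mass concentration; the result is the
    element's mass concentration in the same mass/volume units:
    C * n_atoms * M_element / M_compound.
    """
    if concentration < 0:
        raise ValueError("concentration must be nonnegative")
    return concentration * spec.atoms_of_element * spec.element_molar_mass / spec.compound_molar_mass


def molar_element_yield(molar_conc_um: float, atoms: int, element_molar_mass: float) -> float:
    """Element mass concentration (mg/L) from a molar compound concentration.

    ``molar_conc_um`` is in uM (umol/L); umol/L * g/mol = ug/L, divided by
    1000 to give mg/L.
    """
    if molar_conc_um < 0 or atoms < 0 or element_molar_mass < 0:
        raise ValueError("inputs must be nonnegative")
    return molar_conc_um * atoms * element_molar_mass / 1000.0


def percent_of_theoretical(measured: float, theoretical: float) -> dict:
    """Measured product as a percent of its theoretical stoichiometric maximum."""
    if theoretical <= 0:
        raise ValueError("theoretical yield must be positive")
    raw = 100.0 * measured / theoretical
    return {"percent": round(raw, 1), "raw": raw}


def relative_change(a0: float, at: float) -> dict:
    """Signed percent change of a quantity relative to its initial value."""
    if a0 <= 0:
        raise ValueError("initial value must be positive")
    raw = 100.0 * (at - a0) / a0
    return {"percent": round(raw, 1), "raw": raw}


# ---------------------------------------------------------------------------
# unit handling

_MASS_PER_VOLUME_IN_MG_L = {
    "mg/L": 1.0,
    "ug/L": 1e-3,
    "ng/mL": 1e-3,  # 1 ng/mL == 1 ug/L
    "g/L": 1e3,
    "ug/mL": 1.0,  # 1 ug/mL == 1 mg/L
}


def convert_concentration(value: float, from_unit: str, to_unit: str) -> float:
    """Convert between mass-per-volume concentration units."""
    try:
        f = _MASS_PER_VOLUME_IN_MG_L[from_unit]
        t = _MASS_PER_VOLUME_IN_MG_L[to_unit]
    except KeyError as exc:
        raise ValueError(f"unknown concentration unit: {exc.args[0]!r}") from None
    return value * f / t


def mass_to_molar(mg_per_l: float, molar_mass: float) -> float:
    """mg/L -> uM given the compound's molar mass in g/mol."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return mg_per_l / molar_mass * 1000.0


def molar_to_mass(um: float, molar_mass: float) -> float:
    """uM -> mg/L given the compound's molar mass in g/mol."""
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    return um * molar_mass / 1000.0


# ---------------------------------------------------------------------------
# kinetic fits


def first_order_fit(series: AssaySeries) -> dict:
    """First-order decay fit C(t) = C0 exp(-k t) by log-linear least squares.

    Returns ``{"k": rate constant (1/day), "C0": fitted intercept, "r2": fit
    quality, "degenerate": flag for a constant series}``.
    """
    t = series.times
    c = series.mean
    if t.size < 3:
        raise ValueError("need at least 3 time points")
    if np.any(c <= 0):
        raise ValueError("first-order fit requires strictly positive concentrations")
    logc = np.log(c)
    res = stats.linregress(t, logc)
    degenerate = bool(np.allclose(logc, logc[0]))
    r2 = 1.0 if degenerate else res.rvalue**2
    return {
        "k": -res.slope,
        "C0": float(np.exp(res.intercept)),
        "r2": float(r2),
        "degenerate": degenerate,
    }


def linear_window_fit(series: AssaySeries, t_start: float, t_end: float) -> dict:
    """Ordinary least squares on raw concentrations within [t_start, t_end]."""
    mask = (series.times >= t_start) & (series.times <= t_end)
    t = series.times[mask]
    c = series.mean[mask]
    if t.size < 2:
        raise ValueError("need at least 2 points inside the window")
    res = stats.linregress(t, c)
    # r is nan for an exactly-determined 2-point fit; the line is exact then
    if t.size == 2 or np.allclose(c - (res.intercept + res.slope * t), 0.0):
        r2 = 1.0
    else:
        r2 = res.rvalue**2
    return {"slope": float(res.slope), "intercept": float(res.intercept), "r2": float(r2)}


# ---------------------------------------------------------------------------
# community composition


def diversity_indices(abundances, base: float | None = None) -> dict:
    """Alpha-diversity summary of one composition vector.

    Shannon entropy H = -sum p ln p (natural log by default; pass ``base`` for
    another logarithm base), Simpson diversity D = 1 - sum p^2, and richness
    (count of nonzero taxa). Backed by scikit-bio's implementations.
    """
    p = np.asarray(abundances, dtype=float)
    if np.any(p < 0):
        raise ValueError("abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("abundance vector must have positive total")
    base = math.e if base is None else base
    shannon = float(_skbio_alpha.shannon(p, base=base))
    simpson = float(_skbio_alpha.simpson(p))
    richness = int(np.count_nonzero(p))
    return {"shannon": shannon, "simpson": simpson, "richness": richness}


def bray_curtis(a, b) -> float:
    """Bray-Curtis dissimilarity between two composition vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.sum() == 0 and b.sum() == 0:
        return 0.0
    return float(braycurtis(a, b))


def community_stability_index(table: AbundanceTable, sentinel: float = CSI_SENTINEL) -> dict:
    """Community Stability Index: 1/CV of consecutive Bray-Curtis dissimilarities.

    CV is the coefficient of variation (SD/mean, SD with one delta degree of
    freedom) of the Bray-Curtis dissimilarities between consecutive time
    points; CSI = mean/SD. Degenerate cases (all dissimilarities identical,
    or zero mean) return the capped ``sentinel`` with ``degenerate=True``.
    """
    n_t = table.times.size
    if n_t < 3:
        raise ValueError("need at least 3 time points (2 consecutive dissimilarities)")
    diss = np.array(
        [bray_curtis(table.abundances[i], table.abundances[i + 1]) for i in range(n_t - 1)]
    )
    mean = diss.mean()
    sd = diss.std(ddof=1)
    if mean <= 0 or sd <= 0:
        return {"csi": sentinel, "dissimilarities": diss, "degenerate": True}
    csi = mean / sd
    return {"csi": min(float(csi), sentinel), "dissimilarities": diss, "degenerate": False}
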