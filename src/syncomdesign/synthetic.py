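"""Synthetic strain panels, phenotype labels, pathway maps and assay series.

The generator emulates the data a multi-pollutant community-design study
produces: a strain x enzyme-class count matrix (sparse, overdispersed copy
numbers), a pathway map linking enzyme classes to pollutant-degradation
pathways and to metabolite conversion steps, per-strain per-pollutant
degradation efficiencies in [0, 1] driven by a planted genotype->phenotype
link, and replicate-resolved degradation time series (first-order, biphasic
or sigmoid kinetics). Everything is deterministic under a fixed seed, and
with ``signal_strength = 0`` the labels carry no information about the
genotypes — the null the predictor's permutation tests rely on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assay import AssaySeries

__all__ = [
    "GeneratorConfig",
    "PlantedModel",
    "generate_profiles",
    "generate_labels",
    "generate_assay_series",
    "default_pollutants",
]

#: Pollutant classes targeted by the designed consortium.
DEFAULT_POLLUTANTS = ("lignin", "atrazine", "pfas")


def default_pollutants(n: int) -> list[str]:
    if n <= len(DEFAULT_POLLUTANTS):
        return list(DEFAULT_POLLUTANTS[:n])
    return list(DEFAULT_POLLUTANTS) + [f"pollutant_{i}" for i in range(len(DEFAULT_POLLUTANTS), n)]


@dataclass
class GeneratorConfig:
    """Study-condition knobs of the synthetic panel.

    Defaults mirror the cardinalities of the designed-consortium study this
    package models: 45 strains, 267 annotated enzyme classes, 38 pathway
    metabolites and 3 pollutant classes (lignin, atrazine, PFAS), i.e. 135
    strain-pollutant combinations.
    """

    n_strains: int = 45
    n_enzymes: int = 267
    n_metabolites: int = 38
    n_pollutants: int = 3
    count_dispersion: float = 0.6  # negative-binomial overdispersion of copy numbers
    signal_strength: float = 6.0  # effect size of the planted genotype->phenotype map
    noise_sd: float = 0.02  # additive label noise (efficiency units)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_strains", "n_enzymes", "n_metabolites", "n_pollutants"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if self.count_dispersion <= 0:
            raise ValueError("count_dispersion must be positive")
        if self.signal_strength < 0 or self.noise_sd < 0:
            raise ValueError("signal_strength and noise_sd must be nonnegative")


def _enzyme_ids(n: int) -> list[str]:
    # synthetic EC-style identifiers, unique and lexically sortable
    return [f"EC{(i // 100) + 1}.{(i // 10) % 10 + 1}.{i % 10 + 1}.{i + 1:03d}" for i in range(n)]


def _strain_ids(n: int) -> list[str]:
    return [f"S{i + 1:03d}" for i in range(n)]


def _metabolite_ids(n: int) -> list[str]:
    return [f"M{i + 1:03d}" for i in range(n)]


def generate_profiles(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate the strain x enzyme count matrix and a consistent pathway map.

    Counts are drawn per enzyme family as Bernoulli presence (family-level
    sparsity; many zero columns per strain) times a shifted negative binomial
    for the copy number, reproducing the presence/absence character of
    strain-enzyme associations while keeping integer copy numbers.

    The pathway map is a JSON-serializable dict with keys:

    - ``pollutants``: ordered pollutant names;
    - ``pathways``: pollutant -> list of member enzyme IDs;
    - ``chains``: pollutant -> ordered conversion steps
      ``{"substrate": m, "product": m', "enzymes": [...]}`` over the
      metabolite set (linear degradation chains, pollutant substrate first);
    - ``enzyme_substrate``: list of ``[enzyme, metabolite, kcat]`` pairs with
      catalytic-efficiency weights;
    - ``metabolites``: all metabolite IDs.
    """
    rng = np.random.default_rng(config.seed)
    strains = _strain_ids(config.n_strains)
    enzymes = _enzyme_ids(config.n_enzymes)
    metabolites = _metabolite_ids(config.n_metabolites)
    pollutants = default_pollutants(config.n_pollutants)

    # family-level occupancy: each enzyme family has its own prevalence
    prevalence = rng.beta(2.0, 3.0, size=config.n_enzymes)  # mean 0.4, many sparse
    present = rng.random((config.n_strains, config.n_enzymes)) < prevalence[None, :]
    # copy number given presence: 1 + NB(r, p) with mean ~ 1 extra copy
    r = 1.0 / config.count_dispersion
    p = r / (r + 1.0)
    copies = 1 + rng.negative_binomial(r, p, size=present.shape)
    counts = present * copies
    profiles = pd.DataFrame(counts, index=strains, columns=enzymes, dtype=int)

    # pathway membership: partition a share of enzymes across pollutants,
    # leave the remainder as housekeeping (no pathway)
    n_path_enz = max(config.n_pollutants, int(round(0.35 * config.n_enzymes)))
    path_enzymes = list(rng.choice(config.n_enzymes, size=n_path_enz, replace=False))
    assignment: dict[str, list[str]] = {pol: [] for pol in pollutants}
    for j, idx in enumerate(path_enzymes):
        assignment[pollutants[j % config.n_pollutants]].append(enzymes[idx])
    for pol in pollutants:
        assignment[pol].sort()

    # metabolite chains: split the metabolite pool across pollutants into
    # linear conversion chains; each step catalyzed by 1-2 pathway enzymes
    chain_ids = np.array_split(np.arange(config.n_metabolites), config.n_pollutants)
    chains: dict[str, list[dict]] = {}
    enzyme_substrate: list[list] = []
    for pol, ids in zip(pollutants, chain_ids):
        mets = [metabolites[i] for i in ids]
        steps = []
        pool = assignment[pol]
        for s_i in range(len(mets) - 1):
            if pool:
                k = int(rng.integers(1, min(2, len(pool)) + 1))
                step_enzymes = sorted(rng.choice(pool, size=k, replace=False).tolist())
            else:
                step_enzymes = []
            steps.append({"substrate": mets[s_i], "product": mets[s_i + 1], "enzymes": step_enzymes})
            for e in step_enzymes:
                kcat = float(np.round(rng.lognormal(0.0, 0.5), 4))
                enzyme_substrate.append([e, mets[s_i], kcat])
        chains[pol] = steps

    pathway_map = {
        "pollutants": pollutants,
        "pathways": assignment,
        "chains": chains,
        "enzyme_substrate": enzyme_substrate,
        "metabolites": metabolites,
    }
    return profiles, pathway_map


@dataclass
class PlantedModel:
    """Ground-truth genotype->degradation map used for parameter recovery.

    Efficiency for pollutant c is a rescaled logistic of the pathway-weighted
    mean of log1p enzyme counts ("coverage"): the logistic
    ``sigmoid(slope * (coverage - midpoint))`` is shifted and rescaled so
    that zero coverage maps exactly to ``floor`` and infinite coverage to
    ``ceiling``. The link is bounded in [0, 1] and monotone nondecreasing in
    every weight-positive count; ``slope`` is the planted effect size (a
    zero slope gives a constant link, i.e. labels independent of genotype).
    """

    pathway_weights: dict[str, np.ndarray]  # pollutant -> per-enzyme weights >= 0
    enzymes: list[str]
    slope: float = 6.0
    midpoint: float = 0.4
    floor: float = 0.05
    ceiling: float = 0.95

    @classmethod
    def from_pathway_map(
        cls, pathway_map: dict, enzymes: list[str], signal_strength: float, seed: int = 0
    ) -> "PlantedModel":
        """Plant positive weights on each pollutant's pathway enzymes.

        ``signal_strength`` becomes the link slope; with 0 the weights are
        zeroed too, so labels are independent of the profiles.
        """
        rng = np.random.default_rng(seed)
        idx = {e: j for j, e in enumerate(enzymes)}
        weights = {}
        for pol in pathway_map["pollutants"]:
            w = np.zeros(len(enzymes))
            if signal_strength > 0:
                for e in pathway_map["pathways"][pol]:
                    if e in idx:
                        w[idx[e]] = rng.uniform(0.5, 1.5)
            weights[pol] = w
        return cls(
            pathway_weights=weights, enzymes=list(enzymes), slope=float(signal_strength)
        )

    def coverage(self, profiles: pd.DataFrame) -> pd.DataFrame:
        if list(profiles.columns) != self.enzymes:
            raise ValueError("profile enzyme set does not match the planted model")
        logc = np.log1p(profiles.to_numpy(dtype=float))
        out = {}
        for pol, w in self.pathway_weights.items():
            denom = w.sum()
            out[pol] = (logc @ w) / denom if denom > 0 else np.zeros(len(profiles))
        return pd.DataFrame(out, index=profiles.index)

    def link(self, cov):
        """Rescaled logistic: link(0) = floor exactly, link(inf) = ceiling."""
        cov = np.asarray(cov, dtype=float)
        if self.slope == 0:
            return np.full_like(cov, self.floor)
        sig = 1.0 / (1.0 + np.exp(-self.slope * (cov - self.midpoint)))
        sig0 = 1.0 / (1.0 + np.exp(self.slope * self.midpoint))
        scaled = (sig - sig0) / (1.0 - sig0)
        return self.floor + (self.ceiling - self.floor) * scaled

    def efficiency(self, profiles: pd.DataFrame) -> pd.DataFrame:
        cov = self.coverage(profiles)
        eff = pd.DataFrame(self.link(cov.to_numpy()), index=cov.index, columns=cov.columns)
        return eff.clip(0.0, 1.0)

    def to_dict(self) -> dict:
        return {
            "enzymes": self.enzymes,
            "pathway_weights": {k: v.tolist() for k, v in self.pathway_weights.items()},
            "link": {
                "name": "scaled_logistic",
                "slope": self.slope,
                "midpoint": self.midpoint,
                "floor": self.floor,
                "ceiling": self.ceiling,
            },
        }


def generate_labels(
    profiles: pd.DataFrame, planted: PlantedModel, noise_sd: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Strain x pollutant degradation efficiencies in [0, 1].

    ``noise_sd = 0`` returns the planted link values exactly; otherwise
    additive Gaussian noise is applied before clipping to [0, 1].
    """
    eff = planted.efficiency(profiles)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eff = eff + rng.normal(0.0, noise_sd, size=eff.shape)
    return eff.clip(0.0, 1.0)


# ---------------------------------------------------------------------------
# assay time series


def _curve(model: dict, t: np.ndarray, c0: float) -> np.ndarray:
    kind = model.get("kind")
    if kind == "first_order":
        k = model["k"]
        if k < 0:
            raise ValueError("rate constant must be nonnegative")
        return c0 * np.exp(-k * t)
    if kind == "biphasic":
        k1, k2, tb = model["k1"], model["k2"], model["breakpoint"]
        if k1 < 0 or k2 < 0:
            raise ValueError("rate constants must be nonnegative")
        return c0 * np.exp(-k1 * np.minimum(t, tb)) * np.exp(-k2 * np.maximum(t - tb, 0.0))
    if kind == "sigmoid":
        lag, rate = model["lag"], model["rate"]
        plateau = model.get("plateau", 0.95)
        if rate < 0:
            raise ValueError("rate must be nonnegative")
        # removal fraction follows a logistic with midpoint 2 days past the lag,
        # keeping removal < 5% through the lag period at default rate
        t_mid = lag + 2.0
        removed = plateau / (1.0 + np.exp(-rate * (t - t_mid)))
        return c0 * (1.0 - removed)
    raise ValueError(f"unknown kinetic model kind: {kind!r}")


def generate_assay_series(
    model: dict,
    c0: float,
    days: int,
    n_reps: int = 6,
    noise_sd: float = 0.0,
    seed: int = 0,
    unit: str = "mg/L",
) -> AssaySeries:
    """Replicate-resolved degradation time series under a chosen kinetic law.

    ``model`` is one of ``{"kind": "first_order", "k": ...}``,
    ``{"kind": "biphasic", "k1": ..., "k2": ..., "breakpoint": ...}`` or
    ``{"kind": "sigmoid", "lag": ..., "rate": ..., "plateau": ...}``.
    Replicate noise is additive Gaussian truncated at 0 (n = 6 by default,
    matching +/- SD reporting of bench assays); ``noise_sd = 0`` reproduces
    the closed-form curve exactly.
    """
    if c0 <= 0:
        raise ValueError("initial concentration must be positive")
    if days < 1:
        raise ValueError("days must be >= 1")
    t = np.arange(0.0, days + 1.0)
    curve = _curve(model, t, c0)
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        reps = curve[:, None] + rng.normal(0.0, noise_sd, size=(t.size, n_reps))
        reps = np.clip(reps, 0.0, None)
    else:
        reps = np.repeat(curve[:, None], n_reps, axis=1)
    mean = reps.mean(axis=1)
    sd = reps.std(axis=1, ddof=1) if n_reps > 1 else np.zeros_like(mean)
    return AssaySeries(times=t, mean=mean, sd=sd, n_reps=n_reps, unit=unit, replicates=reps)
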