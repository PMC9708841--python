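"""Synthetic inputs for every pipeline stage.

Real cohort inputs (imputed expression scores, blood metabolic features,
disease follow-up) are access-restricted, so this module generates statistical
stand-ins with known ground truth: toy stoichiometric networks whose solution
spaces are understood exactly, approximately normal log2 gene scores centred
at 0, feature tables that are linear combinations of true fluxes plus
Gaussian noise with planted effect sizes, and survival times with
flux-dependent proportional hazards and right censoring.

All randomness flows from a single master seed; each generator derives an
independent stream via :func:`numpy.random.SeedSequence` spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .network import Metabolite, MetabolicNetwork, Reaction

#: default gene-score standard deviation (log2 units); FC then spans ~[0.5, 2]
DEFAULT_SCORE_SD = 0.25

_STREAMS = {"expression": 0, "scores": 1, "features": 2, "survival": 3, "covariates": 4}


def derived_rng(seed: int | None, stream: str) -> np.random.Generator:
    """A generator for a named component stream derived from the master seed."""
    key = _STREAMS.get(stream)
    if key is None:
        key = abs(hash(stream)) % (2**31)
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


@dataclass
class ToyNetworkSpec:
    """Recipe for a toy network: a named template plus optional overrides."""

    template: str = "toy3"
    bound_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)
    gene_overrides: dict[str, frozenset[str]] = field(default_factory=dict)


def _toy3() -> MetabolicNetwork:
    # One internal metabolite, one source, two competing sinks; the feasible
    # set is the 2-simplex-like polytope {v1 = v2 + v3, 0 <= v <= 10}.
    mets = [Metabolite("A", "c")]
    rxns = [
        Reaction("R1", {"A": 1.0}, 0, 10, subsystem="Exchange reactions", genes={"g1"}),
        Reaction("R2", {"A": -1.0}, 0, 10, subsystem="Glycolysis", genes={"g2a", "g2b"}),
        Reaction("R3", {"A": -1.0}, 0, 10, subsystem="Fatty acid oxidation", genes={"g3"}),
    ]
    return MetabolicNetwork(mets, rxns, id="toy3")


def _branched6() -> MetabolicNetwork:
    # Two alternative internal routes A->B->D and A->C->D; rerouting between
    # them exercises expression-weighted minimisation.
    mets = [Metabolite(m, "c") for m in ("A", "B", "C", "D")]
    rxns = [
        Reaction("R1", {"A": 1.0}, 0, 10, subsystem="Exchange reactions", genes={"g1"}),
        Reaction("R2", {"A": -1.0, "B": 1.0}, 0, 10, subsystem="Glycolysis", genes={"g2"}),
        Reaction("R3", {"A": -1.0, "C": 1.0}, 0, 10, subsystem="Pentose phosphate pathway",
                 genes={"g3"}),
        Reaction("R4", {"B": -1.0, "D": 1.0}, 0, 10, subsystem="Glycolysis", genes={"g4"}),
        Reaction("R5", {"C": -1.0, "D": 1.0}, 0, 10, subsystem="Pentose phosphate pathway",
                 genes={"g5"}),
        Reaction("R6", {"D": -1.0}, 0, 10, subsystem="Exchange reactions", genes={"g6"}),
    ]
    return MetabolicNetwork(mets, rxns, id="branched6")


def _reversible4() -> MetabolicNetwork:
    # Reversible exchanges on both ends plus a reversible interconversion, so
    # material can flow in either direction; exercises reversible splitting.
    mets = [Metabolite(m, "c") for m in ("A", "B")]
    rxns = [
        Reaction("R1", {"A": 1.0}, -10, 10, subsystem="Exchange reactions", genes={"g1"}),
        Reaction("R2", {"A": -1.0, "B": 1.0}, -5, 10, subsystem="Glycolysis",
                 genes={"g2"}),
        Reaction("R3", {"B": -1.0}, -5, 10, subsystem="Exchange reactions", genes={"g3"}),
        Reaction("R4", {"A": -1.0, "B": 1.0}, 0, 5, subsystem="Amino acid metabolism",
                 genes={"g4"}),
    ]
    return MetabolicNetwork(mets, rxns, id="reversible4")


_TEMPLATES = {"toy3": _toy3, "branched6": _branched6, "reversible4": _reversible4}


def make_toy_network(spec: ToyNetworkSpec | str) -> MetabolicNetwork:
    """Build a deterministic toy network from a template name or spec."""
    if isinstance(spec, str):
        spec = ToyNetworkSpec(spec)
    builder = _TEMPLATES.get(spec.template)
    if builder is None:
        raise ValidationError(
            f"unknown toy template {spec.template!r}; available: {sorted(_TEMPLATES)}"
        )
    net = builder()
    for rid, (lb, ub) in spec.bound_overrides.items():
        r = net.reaction(rid)
        r.lb, r.ub = lb, ub
    for rid, genes in spec.gene_overrides.items():
        net.reaction(rid).genes = frozenset(genes)
    net.validate()
    return net


def simulate_expression_profile(
    genes: list[str], seed: int | None = None, mean_log_tpm: float = 3.0, sd_log_tpm: float = 1.0
) -> pd.Series:
    """Log-normal organ-average TPM values, one per gene."""
    rng = derived_rng(seed, "expression")
    tpm = np.exp2(rng.normal(mean_log_tpm, sd_log_tpm, size=len(genes)))
    return pd.Series(tpm, index=list(genes))


def simulate_scores(
    genes: list[str], n_individuals: int, sd: float = DEFAULT_SCORE_SD, seed: int | None = None
) -> pd.DataFrame:
    """I.i.d. Normal(0, sd^2) gene scores (gene x individual), seed-reproducible."""
    if sd < 0:
        raise ValidationError("score sd must be >= 0")
    rng = derived_rng(seed, "scores")
    individuals = [f"ind_{i:04d}" for i in range(n_individuals)]
    data = rng.normal(0.0, sd, size=(len(genes), n_individuals))
    return pd.DataFrame(data, index=list(genes), columns=individuals)


def simulate_features(
    fluxes: pd.DataFrame,
    effects: dict[tuple[str, str], float] | None = None,
    n_features: int = 5,
    noise_sd: float = 1.0,
    seed: int | None = None,
    class_labels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature tables as linear combinations of fluxes plus Gaussian noise.

    ``fluxes`` is individual x reaction (standardised scale); ``effects`` maps
    (reaction id, feature name) to a planted slope.  Features named in
    ``effects`` but beyond ``n_features`` are appended.  Returns the feature
    table (individual x feature) and a Series of class labels per feature
    (defaults to "simulated").
    """
    if noise_sd < 0:
        raise ValidationError("noise sd must be >= 0")
    effects = effects or {}
    rng = derived_rng(seed, "features")
    names = [f"feat_{j:03d}" for j in range(n_features)]
    for _, feat in effects:
        if feat not in names:
            names.append(feat)
    table = pd.DataFrame(
        rng.normal(0.0, noise_sd, size=(fluxes.shape[0], len(names))),
        index=fluxes.index,
        columns=names,
    )
    for (rid, feat), beta in effects.items():
        if rid not in fluxes.columns:
            raise ValidationError(f"planted effect references unknown flux {rid!r}")
        table[feat] = table[feat] + beta * fluxes[rid]
    labels = pd.Series({n: (class_labels or {}).get(n, "simulated") for n in names})
    return table, labels


def simulate_survival(
    fluxes: pd.DataFrame,
    log_hrs: dict[str, float] | None = None,
    baseline_hazard: float = 0.02,
    censoring: float = 0.3,
    seed: int | None = None,
    entry_age_range: tuple[float, float] = (40.0, 70.0),
) -> pd.DataFrame:
    """Survival table with flux-dependent proportional hazards on an age scale.

    Event ages are entry age plus an exponential waiting time with hazard
    ``baseline_hazard * stratum factor * exp(sum log_hrs[i] * flux_i)``; the
    two sex strata carry distinct baselines.  Administrative censoring at a
    common cutoff age is calibrated so that approximately ``censoring`` of
    individuals are censored.  Columns: entry_age, exit_age, event, sex.
    """
    if not 0 <= censoring < 1:
        raise ValidationError("censoring fraction must lie in [0, 1)")
    if baseline_hazard <= 0:
        raise ValidationError("baseline hazard must be > 0")
    log_hrs = log_hrs or {}
    rng = derived_rng(seed, "survival")
    n = fluxes.shape[0]
    entry = rng.uniform(*entry_age_range, size=n)
    sex = rng.integers(0, 2, size=n)  # 0 = female, 1 = male
    lp = np.zeros(n)
    for rid, b in log_hrs.items():
        if rid not in fluxes.columns:
            raise ValidationError(f"planted log-HR references unknown flux {rid!r}")
        lp += b * fluxes[rid].to_numpy(dtype=float)
    hazard = baseline_hazard * np.where(sex == 1, 1.4, 1.0) * np.exp(lp)
    event_age = entry + rng.exponential(1.0 / hazard)
    if censoring > 0:
        cutoff = float(np.quantile(event_age, 1.0 - censoring))
        cutoff = max(cutoff, float(entry.max()) + 1e-6)
    else:
        cutoff = np.inf
    exit_age = np.minimum(event_age, cutoff)
    event = event_age <= cutoff
    return pd.DataFrame(
        {
            "entry_age": entry,
            "exit_age": exit_age,
            "event": event,
            "sex": np.where(sex == 1, "male", "female"),
        },
        index=fluxes.index,
    )


@dataclass
class SimulationConfig:
    """Study-condition knobs for a full synthetic cohort."""

    n_individuals: int = 200
    score_sd: float = DEFAULT_SCORE_SD
    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    n_features: int = 5
    noise_sd: float = 1.0
    log_hrs: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.02
    censoring: float = 0.3
    seed: int | None = None

    def __post_init__(self):
        if self.score_sd <= 0 or self.noise_sd <= 0:
            raise ValidationError("standard deviations must be > 0")
        if not 0 <= self.censoring < 1:
            raise ValidationError("censoring fraction must lie in [0, 1)")
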