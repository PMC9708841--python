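"""Fluxome-wide association studies (FWAS).

Standardised personal flux values are associated with (i) quantitative
blood-feature measurements through per-pair linear regression
``Met = a * v + e`` with a two-tailed t-test on the slope, and (ii)
time-to-event outcomes through sex-stratified Cox proportional-hazards
regression on an age time scale with a two-tailed Wald test on the flux
hazard ratio.  p values are Benjamini-Hochberg adjusted within each analysis
family (all flux x feature pairs jointly; all fluxes for the Cox screen).

Supporting steps: covariate residualisation and quality filters for feature
tables, greedy pruning of collinear columns, one-sided Fisher enrichment of
hit sets, and the annotation of transport reactions with the metabolic
system of the metabolites they move (with cofactors down-weighted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ValidationError
from .network import MetabolicNetwork

DEFAULT_LINEAR_THRESHOLD = 1e-6
DEFAULT_COX_THRESHOLD = 0.05
DEFAULT_FLUX_PRUNE = 0.9
DEFAULT_FEATURE_PRUNE = 0.75
MAX_MISSING_FRACTION = 0.75
MAX_SD_LOG2_RATIO = float(np.log2(2.5))

#: metabolites that usually ride along in transport processes
DEFAULT_COFACTORS = frozenset(
    {"na1", "k", "h", "atp", "adp", "pi", "h2o", "na+", "k+", "h+"}
)
DEFAULT_COFACTOR_WEIGHT = 0.1
MISC_SYSTEM = "Miscellaneous"


# -- multiple testing ------------------------------------------------------


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_adjust expects a 1-D array of p values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


# -- feature preprocessing -------------------------------------------------


@dataclass
class FeatureTable:
    """Preprocessed feature matrix (individual x feature) with class labels."""

    values: pd.DataFrame
    classes: pd.Series
    dropped: dict[str, list[str]]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.columns)


def preprocess_features(
    raw: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    classes: pd.Series | None = None,
    sd_other: pd.Series | None = None,
    max_missing: float = MAX_MISSING_FRACTION,
    max_sd_log2_ratio: float = MAX_SD_LOG2_RATIO,
) -> FeatureTable:
    """Quality-filter, residualise and standardise a feature table.

    Features with more than ``max_missing`` missing values are dropped, as
    are features whose standard deviation differs from a second cohort's
    (``sd_other``) by more than ``max_sd_log2_ratio`` on the log2 scale.
    Remaining features are residualised on the covariates by ordinary least
    squares (rows with missing values excluded per feature) and z-scored
    with the sample standard deviation.
    """
    dropped: dict[str, list[str]] = {"missing": [], "variance_ratio": [], "constant": []}
    work = raw.astype(float).copy()
    for col in list(work.columns):
        if work[col].isna().mean() > max_missing:
            dropped["missing"].append(col)
    work = work.drop(columns=dropped["missing"])
    if sd_other is not None:
        for col in list(work.columns):
            other = sd_other.get(col)
            self_sd = work[col].std(ddof=1)
            if other is None or other <= 0 or self_sd <= 0:
                continue
            if abs(np.log2(self_sd / other)) > max_sd_log2_ratio:
                dropped["variance_ratio"].append(col)
        work = work.drop(columns=dropped["variance_ratio"])
    if covariates is not None:
        if covariates.isna().any().any():
            raise ValidationError("covariate columns must be complete")
        X = np.column_stack(
            [np.ones(len(covariates))] + [covariates[c].to_numpy(float) for c in covariates]
        )
        X = pd.DataFrame(X, index=covariates.index)
        for col in work.columns:
            y = work[col]
            rows = y.dropna().index.intersection(X.index)
            Xr = X.loc[rows].to_numpy()
            beta, *_ = np.linalg.lstsq(Xr, y.loc[rows].to_numpy(), rcond=None)
            resid = pd.Series(np.nan, index=work.index)
            resid.loc[rows] = y.loc[rows].to_numpy() - Xr @ beta
            work[col] = resid
    for col in list(work.columns):
        sd = work[col].std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            dropped["constant"].append(col)
            continue
        work[col] = (work[col] - work[col].mean()) / sd
    work = work.drop(columns=dropped["constant"])
    if work.shape[1] == 0:
        raise ValidationError("preprocessing dropped every feature")
    if classes is None:
        classes = pd.Series("unknown", index=work.columns)
    else:
        classes = classes.reindex(work.columns).fillna("unknown")
    return FeatureTable(work, classes, dropped)


# -- collinearity pruning --------------------------------------------------


def prune_correlated(columns: pd.DataFrame, threshold: float) -> list[str]:
    """Greedy removal of collinear columns.

    While any pair of columns has |Pearson rho| above the threshold, the
    member of the most correlated pair with the larger mean absolute
    correlation to all remaining columns is removed (ties break towards the
    lexicographically larger id so the survivor set is deterministic).
    Correlations use complete observations per pair.
    """
    if columns.shape[0] < 2:
        raise ValidationError("pruning needs at least two rows")
    kept = sorted(columns.columns)
    corr = columns[kept].corr().abs()
    np.fill_diagonal(corr.values, 0.0)
    corr = corr.fillna(0.0)
    while True:
        sub = corr.loc[kept, kept]
        if sub.size == 0 or float(sub.values.max()) <= threshold:
            return kept
        i, j = np.unravel_index(np.argmax(sub.values), sub.shape)
        a, b = sub.index[i], sub.columns[j]
        mean_a = sub.loc[a].mean()
        mean_b = sub.loc[b].mean()
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = max(a, b)
        kept = [c for c in kept if c != drop]


# -- linear FWAS -----------------------------------------------------------


@dataclass
class AssociationResults:
    """Per (flux, outcome) association estimates with FDR control."""

    table: pd.DataFrame
    threshold: float
    family: str

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] < self.threshold]

    def summary(self, top: int = 10) -> pd.DataFrame:
        return self.table.sort_values("adjusted_p").head(top)


def fwas_linear(
    fluxes: pd.DataFrame,
    features: pd.DataFrame,
    threshold_adj_p: float = DEFAULT_LINEAR_THRESHOLD,
    min_overlap: int = 10,
) -> AssociationResults:
    """Associate every flux with every feature by simple linear regression.

    An intercept is always fitted (with exactly centred inputs it is ~0 and
    leaves the slope unchanged); significance is a two-tailed t-test on the
    slope and adjustment is Benjamini-Hochberg across all tested pairs
    jointly.  Zero-variance flux columns are skipped with a note.
    """
    common = fluxes.index.intersection(features.index)
    if len(common) < min_overlap:
        raise ValidationError(
            f"only {len(common)} overlapping individuals (need >= {min_overlap})"
        )
    X = fluxes.loc[common]
    records, skipped = [], []
    for feat in features.columns:
        y_full = features.loc[common, feat]
        obs = y_full.dropna().index
        y = y_full.loc[obs].to_numpy(float)
        n = len(obs)
        if n < min_overlap:
            continue
        Xo = X.loc[obs].to_numpy(float)
        xm = Xo.mean(axis=0)
        xc = Xo - xm
        sxx = (xc**2).sum(axis=0)
        ym = y.mean()
        yc = y - ym
        syy = float((yc**2).sum())
        zero = sxx <= 0
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (xc * yc[:, None]).sum(axis=0) / sxx
            sse = syy - slope**2 * sxx
            sse = np.maximum(sse, 0.0)
            df = n - 2
            se = np.sqrt(sse / df / sxx)
            tstat = slope / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df)
        # perfect fits: se 0 -> t inf -> p 0
        p = np.where(np.isfinite(tstat), p, 0.0)
        r2 = np.where(syy > 0, slope**2 * sxx / syy, 0.0)
        for k, rid in enumerate(X.columns):
            if zero[k]:
                skipped.append((rid, feat))
                continue
            records.append(
                {
                    "flux": rid,
                    "feature": feat,
                    "effect": slope[k],
                    "se": se[k] if np.isfinite(se[k]) else 0.0,
                    "statistic": tstat[k],
                    "p": float(p[k]),
                    "r_squared": float(r2[k]),
                    "n": n,
                }
            )
    if skipped:
        warnings.warn(f"skipped {len(skipped)} zero-variance flux-feature pairs")
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p"].to_numpy())
    else:
        table = pd.DataFrame(
            columns=["flux", "feature", "effect", "se", "statistic", "p",
                     "r_squared", "n", "adjusted_p"]
        )
    return AssociationResults(table, threshold_adj_p, family="flux x feature pairs")


class LinearFwas:
    """Model wrapper: ``LinearFwas(fluxes, features).fit()``."""

    def __init__(self, fluxes: pd.DataFrame, features, min_overlap: int = 10):
        self.fluxes = fluxes
        self.features = features.values if isinstance(features, FeatureTable) else features
        self.min_overlap = min_overlap

    def fit(self, threshold_adj_p: float = DEFAULT_LINEAR_THRESHOLD) -> AssociationResults:
        return fwas_linear(
            self.fluxes, self.features, threshold_adj_p, self.min_overlap
        )


# -- Cox FWAS --------------------------------------------------------------


def fwas_cox(
    fluxes: pd.DataFrame,
    survival: pd.DataFrame,
    covariates: list[str] = (),
    stratum_col: str = "sex",
    entry_col: str = "entry_age",
    duration_col: str = "exit_age",
    event_col: str = "event",
    threshold_adj_p: float = DEFAULT_COX_THRESHOLD,
) -> AssociationResults:
    """Screen fluxes against a time-to-event outcome.

    One Cox proportional-hazards model per flux, with age as the time scale
    (left truncation at entry age), stratified by ``stratum_col`` and
    adjusted for the listed covariate columns of ``survival``.  Significance
    is a two-tailed Wald test on the flux log hazard ratio; adjustment is
    Benjamini-Hochberg across all converged fluxes.  Non-converging fluxes
    are flagged and excluded from the FDR family with a warning.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    required = {stratum_col, entry_col, duration_col, event_col, *covariates}
    missing = required - set(survival.columns)
    if missing:
        raise ValidationError(f"survival table lacks columns {sorted(missing)}")
    common = fluxes.index.intersection(survival.index)
    surv = survival.loc[common]
    events_per_stratum = surv.groupby(stratum_col)[event_col].sum()
    if (events_per_stratum < 2).any():
        raise ValidationError(
            f"need >= 2 events per stratum, got {events_per_stratum.to_dict()}"
        )
    records, failed = [], []
    for rid in fluxes.columns:
        frame = surv[[entry_col, duration_col, event_col, stratum_col, *covariates]].copy()
        frame["flux"] = fluxes.loc[common, rid]
        frame = frame.dropna()
        fitter = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fitter.fit(
                    frame,
                    duration_col=duration_col,
                    event_col=event_col,
                    entry_col=entry_col,
                    strata=[stratum_col],
                )
        except (ConvergenceError, np.linalg.LinAlgError, ValueError) as exc:
            failed.append((rid, str(exc)))
            continue
        row = fitter.summary.loc["flux"]
        records.append(
            {
                "flux": rid,
                "log_hr": float(row["coef"]),
                "hazard_ratio": float(np.exp(row["coef"])),
                "se": float(row["se(coef)"]),
                "statistic": float(row["z"]),
                "p": float(row["p"]),
                "n": len(frame),
                "n_events": int(frame[event_col].sum()),
            }
        )
    if failed:
        warnings.warn(
            f"Cox fit failed for {len(failed)} fluxes (excluded from FDR family): "
            f"{[rid for rid, _ in failed][:5]}"
        )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table["adjusted_p"] = bh_adjust(table["p"].to_numpy())
    return AssociationResults(table, threshold_adj_p, family="fluxes (survival)")


class CoxFwas:
    """Model wrapper: ``CoxFwas(fluxes, survival).fit()``."""

    def __init__(
        self,
        fluxes: pd.DataFrame,
        survival: pd.DataFrame,
        covariates: list[str] = (),
        stratum_col: str = "sex",
    ):
        self.fluxes = fluxes
        self.survival = survival
        self.covariates = list(covariates)
        self.stratum_col = stratum_col

    def fit(self, threshold_adj_p: float = DEFAULT_COX_THRESHOLD) -> AssociationResults:
        return fwas_cox(
            self.fluxes,
            self.survival,
            covariates=self.covariates,
            stratum_col=self.stratum_col,
            threshold_adj_p=threshold_adj_p,
        )


# -- enrichment ------------------------------------------------------------


def one_sided_fisher_p(hits_in: int, hits_out: int, nonhits_in: int, nonhits_out: int) -> float:
    """One-sided (greater) Fisher exact p for a 2x2 {in,out} x {hit,non-hit}
    table: the upper hypergeometric tail P(X >= hits_in)."""
    counts = (hits_in, hits_out, nonhits_in, nonhits_out)
    if any(c < 0 for c in counts):
        raise ValidationError("table counts must be non-negative")
    N = sum(counts)
    K = hits_in + nonhits_in
    n = hits_in + hits_out
    return float(min(stats.hypergeom.sf(hits_in - 1, N, K, n), 1.0))


def fisher_enrichment(
    hits: set,
    universe: set,
    groups: dict | pd.Series,
    threshold_adj_p: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of a hit set within labelled groups.

    Items of the universe without a label are excluded.  For each label the
    2x2 table {in-label, out-of-label} x {hit, non-hit} is tested against
    over-representation of hits (hypergeometric upper tail); adjustment is
    Benjamini-Hochberg across the labels tested in this call (pool calls
    before adjusting to form larger families, e.g. labels x organs).
    """
    if isinstance(groups, pd.Series):
        groups = groups.to_dict()
    if not universe:
        raise ValidationError("empty universe")
    if not set(hits) <= set(universe):
        raise ValidationError("hits must be a subset of the universe")
    annotated = {i for i in universe if groups.get(i) is not None}
    hits = set(hits) & annotated
    labels = sorted({groups[i] for i in annotated})
    N, n_hits = len(annotated), len(hits)
    records = []
    for label in labels:
        members = {i for i in annotated if groups[i] == label}
        a = len(hits & members)
        K = len(members)
        table = {
            "hits_in": a,
            "hits_out": n_hits - a,
            "nonhits_in": K - a,
            "nonhits_out": N - K - (n_hits - a),
        }
        records.append({"label": label, **table, "p": one_sided_fisher_p(**table)})
    table = pd.DataFrame.from_records(records)
    table["adjusted_p"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = table["adjusted_p"] < threshold_adj_p
    return table


# -- reaction-system annotation -------------------------------------------


def assign_metabolite_system(
    net: MetabolicNetwork,
    subsystem_merge: dict[str, str] | None = None,
    transport_subsystems: set[str] = frozenset({"Transport reactions", "Exchange reactions"}),
) -> tuple[pd.Series, pd.Series]:
    """Label each metabolite with the modal system of its reactions.

    Reaction subsystems are first merged into coarser systems via
    ``subsystem_merge`` (identity by default); transport/exchange reactions
    do not vote.  Ties go to the lexicographically smallest system with a
    tie flag; metabolites in no annotated reaction get "Miscellaneous".
    Returns (labels, tie flags) indexed by metabolite id.
    """
    merge = subsystem_merge or {}
    votes: dict[str, dict[str, int]] = {m.id: {} for m in net.metabolites}
    for r in net.reactions:
        if r.subsystem in transport_subsystems or net.is_exchange(r):
            continue
        system = merge.get(r.subsystem, r.subsystem)
        if not system:
            continue
        for mid in r.stoich:
            votes[mid][system] = votes[mid].get(system, 0) + 1
    labels, ties = {}, {}
    for mid, counts in votes.items():
        if not counts:
            labels[mid], ties[mid] = MISC_SYSTEM, False
            continue
        top = max(counts.values())
        winners = sorted(s for s, c in counts.items() if c == top)
        labels[mid] = winners[0]
        ties[mid] = len(winners) > 1
    return pd.Series(labels), pd.Series(ties)


def assign_transport_system(
    net: MetabolicNetwork,
    metabolite_labels: pd.Series,
    cofactors: set[str] = DEFAULT_COFACTORS,
    cofactor_weight: float = DEFAULT_COFACTOR_WEIGHT,
    transport_subsystems: set[str] = frozenset({"Transport reactions", "Exchange reactions"}),
) -> tuple[pd.Series, pd.Series]:
    """Label transport/exchange reactions by the systems of their cargo.

    Each transported metabolite votes for its system with weight 1, or
    ``cofactor_weight`` (< 1) if it is a common transport cofactor (Na+, K+,
    H+, ATP/ADP, ...), so e.g. an alanine-sodium symporter inherits the
    amino-acid system from alanine rather than Miscellaneous from sodium.
    Weighted ties go to Miscellaneous with a tie flag.  Returns (labels,
    tie flags) indexed by reaction id.
    """
    if not cofactor_weight < 1:
        raise ValidationError("cofactor weight must be < 1")
    cofactors = {c.lower() for c in cofactors}
    labels, ties = {}, {}
    for r in net.reactions:
        if not (r.subsystem in transport_subsystems or net.is_exchange(r)):
            continue
        weights: dict[str, float] = {}
        for mid in r.stoich:
            system = metabolite_labels.get(mid, MISC_SYSTEM)
            base = mid.split("[")[0].split("_")[0].lower()
            wgt = cofactor_weight if base in cofactors or mid.lower() in cofactors else 1.0
            weights[system] = weights.get(system, 0.0) + wgt
        if not weights:
            labels[r.id], ties[r.id] = MISC_SYSTEM, False
            continue
        top = max(weights.values())
        winners = sorted(s for s, v in weights.items() if abs(v - top) < 1e-12)
        if len(winners) > 1:
            labels[r.id], ties[r.id] = MISC_SYSTEM, True
        else:
            labels[r.id], ties[r.id] = winners[0], False
    return pd.Series(labels, dtype=object), pd.Series(ties, dtype=bool)
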