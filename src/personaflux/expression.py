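"""Gene-level abundances and scores mapped to reaction-level quantities.

Two mappings live here.  For the organ *reference* state, average transcript
abundances (TPM) of all isoenzymes and subunits of a reaction are summed and
log2-transformed into a reaction expression value x̄, the input to
expression-weighted flux minimisation.  For *individuals*, per-gene scores
S_{g,n} (log2 relative expression imputed from genotype) are converted into a
reaction activity fold change

    FC_{R,n} = sum_{g in g_R} GTEx_g * 2^{S_{g,n}} / sum_{g in g_R} GTEx_g

i.e. an abundance-weighted mean of the per-gene fold changes, so that highly
expressed isoenzymes dominate the imputed activity change of the reaction.

Boolean AND/OR structure of gene-reaction rules is deliberately flattened to
a plain gene set whose abundances are summed; complex (AND) semantics are not
modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .network import MetabolicNetwork

#: pseudocount inside log2 when summing TPMs, guarding all-zero gene sets
DEFAULT_PSEUDOCOUNT = 1.0


@dataclass
class ReactionExpression:
    """Reaction-level expression x̄ = log2(pseudocount + sum of gene TPMs).

    ``values`` covers reactions with at least one annotated gene; reactions
    with an empty gene set are listed in ``unmapped``.
    """

    values: pd.Series
    unmapped: list[str]
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    @property
    def mapped_ids(self) -> list[str]:
        return list(self.values.index)


def average_source_sites(profiles: list[pd.Series]) -> pd.Series:
    """Average several source-site expression profiles into one organ profile.

    The gene universe is the union of the sites; a gene absent from a site
    contributes 0 to the mean (absence is treated as no expression).
    """
    if not profiles:
        raise ValidationError("average_source_sites: need at least one profile")
    frame = pd.concat([p.astype(float) for p in profiles], axis=1)
    return frame.fillna(0.0).mean(axis=1)


def score_genotypes(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.DataFrame:
    """Impute per-individual gene scores from variant dosages.

    ``dosages`` is variant x individual with allele dosages in [0, 2];
    ``weights`` has columns (gene, variant, weight), one row per variant used
    by a gene's expression model.  Returns gene x individual scores
    S_{g,n} = sum_variants weight * dosage.  Variants missing from the dosage
    matrix count as dosage 0, with a warning.
    """
    required = {"gene", "variant", "weight"}
    if not required.issubset(weights.columns):
        raise ValidationError(f"weight table must have columns {sorted(required)}")
    missing = sorted(set(weights["variant"]) - set(dosages.index))
    if missing:
        warnings.warn(f"{len(missing)} model variants absent from dosages (treated as 0): "
                      f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    full = dosages.reindex(weights["variant"].unique()).fillna(0.0)
    out = {}
    for gene, grp in weights.groupby("gene", sort=True):
        w = grp.set_index("variant")["weight"].astype(float)
        out[gene] = full.loc[w.index].mul(w, axis=0).sum(axis=0)
    return pd.DataFrame(out).T


def map_expression_to_reactions(
    profile: pd.Series,
    net: MetabolicNetwork,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ReactionExpression:
    """Sum gene abundances per reaction and log2-transform.

    Genes annotated on a reaction but absent from the profile contribute 0
    TPM.  Reactions without gene annotations are flagged unmapped and get no
    x̄ value.
    """
    if (profile.dropna() < 0).any():
        raise ValidationError("expression profile contains negative abundances")
    values, unmapped = {}, []
    for r in net.reactions:
        if not r.genes:
            unmapped.append(r.id)
            continue
        total = float(profile.reindex(sorted(r.genes)).fillna(0.0).sum())
        values[r.id] = float(np.log2(pseudocount + total))
    return ReactionExpression(pd.Series(values, dtype=float), unmapped, pseudocount)


def compute_fold_changes(
    scores: pd.DataFrame,
    profile: pd.Series,
    net: MetabolicNetwork,
) -> pd.DataFrame:
    """Reaction activity fold changes FC_{R,n} (reaction x individual).

    Each reaction's fold change is the GTEx-abundance-weighted mean of the
    per-gene fold changes 2^{S_{g,n}} over its gene set.  Genes without a
    score get S = 0 (fold change contribution 1), so sparsely imputable
    reactions default towards no change.  Reactions whose gene set has zero
    total abundance get the neutral value 1; reactions without genes are
    absent from the output.
    """
    if not np.isfinite(scores.to_numpy(dtype=float)).all():
        raise ValidationError("gene score matrix contains non-finite entries")
    individuals = scores.columns
    rows = {}
    for r in net.reactions:
        if not r.genes:
            continue
        genes = sorted(r.genes)
        gtex = profile.reindex(genes).fillna(0.0).to_numpy(dtype=float)
        total = gtex.sum()
        if total <= 0:
            rows[r.id] = np.ones(len(individuals))
            continue
        s = scores.reindex(genes).fillna(0.0).to_numpy(dtype=float)
        rows[r.id] = gtex @ np.exp2(s) / total
    return pd.DataFrame(rows, index=individuals).T
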