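"""Parametric gene-set enrichment: per-sample set scores + sample-level tests.

Instead of a rank/permutation statistic, each gene set gets an activation
score in every sample: genes are first converted to log-ratios against their
own WT-group mean, and the set score in a sample is the one-sample t of the
member ratios against zero. The resulting set × sample score matrix is then
analysed exactly like the gene-level expression matrix (moderated t on the
KO−WT contrast, BH-FDR), yielding per-set enrichment estimates with a
positive/negative direction. The contrast of scores is reported as the set
"fold change".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from fibroprog.diffexpr import (
    KO_LABEL,
    WT_LABEL,
    ExpressionStudy,
    estimate_eb_prior,
    fit_gene_models,
    moderated_stats,
)

#: floor on the within-set standard deviation of member ratios, so that a
#: set whose members move in perfect lockstep still gets a finite score
SD_FLOOR = 1e-8

PROVENANCES = {"kegg", "reactome", "tf", "custom"}


@dataclass
class GeneSetCollection:
    """Named gene sets with a provenance tag."""

    sets: dict[str, list[str]]
    provenance: str = "custom"
    #: per-set count of members dropped because they were absent from the
    #: expression matrix (populated by :func:`build_collection`)
    removed_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def member_counts(self) -> dict[str, int]:
        return {name: len(m) for name, m in self.sets.items()}


@dataclass
class SetScoreMatrix:
    """Set × sample activation scores with the member count used per set."""

    score: pd.DataFrame
    member_counts: dict[str, int]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT file (name, description, members...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} in GMT")
            sets[name] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_tf_table(path: str | Path) -> dict[str, list[str]]:
    """Read a factor→target TSV (factor_id, factor_name, target_gene) and
    merge records by factor ID irrespective of binding site, returning one
    set per factor (union of targets)."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    required = {"factor_id", "target_gene"}
    if not required <= set(tab.columns):
        raise ValueError(f"TF table needs columns {sorted(required)}")
    merged: dict[str, list[str]] = {}
    for fid, sub in tab.groupby("factor_id", sort=True):
        seen: dict[str, None] = dict.fromkeys(sub["target_gene"].astype(str))
        merged[str(fid)] = list(seen)
    return merged


def merge_tf_records(raw_sets: dict[str, list[str]]) -> dict[str, list[str]]:
    """Merge TF record sets whose names share a factor ID.

    Record names of the form ``"FACTOR|site"`` are merged to a single set
    named ``"FACTOR"`` holding the union of targets (first-seen order).
    """
    merged: dict[str, dict[str, None]] = {}
    for name, members in raw_sets.items():
        factor = name.split("|", 1)[0]
        bucket = merged.setdefault(factor, {})
        for g in members:
            bucket.setdefault(g)
    return {factor: list(members) for factor, members in merged.items()}


def build_collection(
    raw_sets: dict[str, list[str]],
    expressed_genes,
    min_size: int = 5,
    provenance: str = "custom",
) -> GeneSetCollection:
    """Intersect sets with the expressed genes and drop small sets.

    For TF provenance, records sharing a factor ID are merged to the union
    of their targets *before* the size filter, so merged factors can pass
    the minimum-size rule even if individual binding-site records do not.
    """
    if provenance == "tf":
        raw_sets = merge_tf_records(raw_sets)
    expressed = set(expressed_genes)
    sets: dict[str, list[str]] = {}
    removed: dict[str, int] = {}
    for name, members in raw_sets.items():
        unique = list(dict.fromkeys(members))
        present = [g for g in unique if g in expressed]
        removed[name] = len(unique) - len(present)
        if len(present) >= min_size:
            sets[name] = present
    if not sets:
        raise ValueError(
            f"no gene set has >= {min_size} members present in the expression data"
        )
    removed = {name: removed[name] for name in sets}
    return GeneSetCollection(sets=sets, provenance=provenance, removed_counts=removed)


def pgsea_scores(
    study: ExpressionStudy,
    collection: GeneSetCollection,
    sd_floor: float = SD_FLOOR,
) -> SetScoreMatrix:
    """Per-sample set activation scores.

    Gene ratios are expression minus the gene's WT-group mean within the
    study; the score of set s in sample j is mean(ratios)·√m / sd(ratios)
    over the m member ratios, with the sd floored at ``sd_floor``.
    """
    wt_mean = study.matrix.loc[:, (study.group == WT_LABEL).to_numpy()].mean(axis=1)
    ratios = study.matrix.sub(wt_mean, axis=0)
    rows = []
    counts: dict[str, int] = {}
    for name, members in collection.sets.items():
        sub = ratios.loc[members].to_numpy(float)
        m = sub.shape[0]
        if m < 2:
            raise RuntimeError(
                f"set {name!r} reached scoring with {m} member(s); "
                "collections must be size-filtered first"
            )
        mean = sub.mean(axis=0)
        sd = np.maximum(sub.std(axis=0, ddof=1), sd_floor)
        score = np.where(mean == 0, 0.0, mean * np.sqrt(m) / sd)
        rows.append(score)
        counts[name] = m
    score = pd.DataFrame(
        np.vstack(rows), index=list(collection.sets), columns=study.samples
    )
    return SetScoreMatrix(score=score, member_counts=counts)


def set_inference(
    scores: SetScoreMatrix,
    group: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated inference on the score matrix, same machinery as for genes.

    Returns a table indexed by set name with columns est (KO−WT score
    contrast, the set "fold change"), t, p, fdr, direction (pos/neg/ns), m.
    """
    pseudo = ExpressionStudy(matrix=scores.score, group=group, model_label="sets")
    fit = fit_gene_models(pseudo)
    prior = estimate_eb_prior(fit.s2, fit.df)
    table = moderated_stats(fit, prior, alpha=alpha)
    table = table.rename(columns={"logFC": "est"})
    table["direction"] = table["direction"].map(
        {"up": "pos", "down": "neg", "ns": "ns"}
    )
    table["m"] = pd.Series(scores.member_counts)
    return table.loc[:, ["est", "t", "p", "fdr", "direction", "m"]]


def run_set_enrichment(
    study: ExpressionStudy,
    raw_sets: dict[str, list[str]],
    min_size: int = 5,
    provenance: str = "custom",
    alpha: float = 0.05,
    sd_floor: float = SD_FLOOR,
) -> pd.DataFrame:
    """Build → score → test in one call for a single study."""
    coll = build_collection(
        raw_sets, study.genes, min_size=min_size, provenance=provenance
    )
    scores = pgsea_scores(study, coll, sd_floor=sd_floor)
    return set_inference(scores, study.group, alpha=alpha)


def write_enrichment_table(
    table: pd.DataFrame, path: str | Path, model_label: str, provenance: str
) -> None:
    out = table.copy()
    out.insert(0, "set", out.index)
    with open(path, "w") as fh:
        fh.write(f"# set enrichment, model={model_label}, provenance={provenance}\n")
        out.to_csv(fh, sep="\t", index=False)
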