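"""Cross-model comparison: direction partitions, Venn regions, asymmetric
similarity ratios, scaling + hierarchical clustering, and sign-concordance
against an external enrichment reference.

The similarity between two models is deliberately non-symmetric: the number
of shared significant changes is divided by each model's own total, so each
pair is summarized by two ratios (one per perspective), separately for
positive and negative changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

_UP_VALUES = {"up", "pos"}
_DOWN_VALUES = {"down", "neg"}

MAX_VENN_MODELS = 6


@dataclass
class DirectionPartition:
    """Per-model identifier sets split by direction of change."""

    up: dict[str, set[str]]
    down: dict[str, set[str]]

    @property
    def models(self) -> list[str]:
        return list(self.up)


def partition(results: dict[str, pd.DataFrame]) -> DirectionPartition:
    """Split each model's result table by its ``direction`` column.

    Accepts gene tables (up/down/ns) and set tables (pos/neg/ns) alike.
    """
    up: dict[str, set[str]] = {}
    down: dict[str, set[str]] = {}
    for model, table in results.items():
        d = table["direction"]
        up[model] = set(table.index[d.isin(_UP_VALUES)])
        down[model] = set(table.index[d.isin(_DOWN_VALUES)])
    return DirectionPartition(up=up, down=down)


def venn_counts(sets: dict[str, set[str]], with_members: bool = False) -> pd.DataFrame:
    """Exact counts for every non-empty region of the Venn partition.

    A region is the subset of models whose sets contain an identifier and
    whose complement sets do not; regions are labelled by "&"-joined model
    names. Refuses more than 6 models.
    """
    models = list(sets)
    if len(models) < 2:
        raise ValueError("Venn partition needs at least 2 models")
    if len(models) > MAX_VENN_MODELS:
        raise ValueError(
            f"refusing Venn partition over {len(models)} models "
            f"(maximum {MAX_VENN_MODELS})"
        )
    membership: dict[str, frozenset[str]] = {}
    for ident in set().union(*sets.values()):
        region = frozenset(m for m in models if ident in sets[m])
        membership.setdefault(ident, region)
    records = []
    for r in range(1, len(models) + 1):
        for combo in combinations(models, r):
            region = frozenset(combo)
            members = sorted(i for i, reg in membership.items() if reg == region)
            record = {"region": "&".join(combo), "n_models": r, "count": len(members)}
            if with_members:
                record["members"] = ",".join(members)
            records.append(record)
    return pd.DataFrame.from_records(records)


def venn_marginals(venn: pd.DataFrame, models: list[str]) -> dict[str, int]:
    """Per-model totals recovered by summing regions containing the model."""
    out = {}
    for m in models:
        mask = venn["region"].map(lambda r: m in r.split("&"))
        out[m] = int(venn.loc[mask, "count"].sum())
    return out


@dataclass
class SimilarityMatrixPair:
    """Row-normalized overlap ratios for positive and negative changes.

    Entry [a, b] is |set_a ∩ set_b| / |set_a|: the fraction of model a's
    significant changes shared with model b, so the matrix is generally
    non-symmetric. The diagonal is exactly 1 for non-empty sets; rows of
    models with no significant changes are set to 0 and flagged.
    """

    pos: pd.DataFrame
    neg: pd.DataFrame
    counts: pd.DataFrame  # per-model up/down totals
    empty_rows: dict[str, list[str]] = field(default_factory=dict)


def _ratio_matrix(sets: dict[str, set[str]]) -> tuple[pd.DataFrame, list[str]]:
    models = list(sets)
    mat = pd.DataFrame(0.0, index=models, columns=models)
    empty = []
    for a in models:
        if not sets[a]:
            empty.append(a)
            continue
        for b in models:
            mat.at[a, b] = len(sets[a] & sets[b]) / len(sets[a])
    return mat, empty


def similarity_matrices(part: DirectionPartition) -> SimilarityMatrixPair:
    pos, empty_pos = _ratio_matrix(part.up)
    neg, empty_neg = _ratio_matrix(part.down)
    counts = pd.DataFrame(
        {
            "up": {m: len(part.up[m]) for m in part.models},
            "down": {m: len(part.down[m]) for m in part.models},
        }
    )
    return SimilarityMatrixPair(
        pos=pos,
        neg=neg,
        counts=counts,
        empty_rows={"pos": empty_pos, "neg": empty_neg},
    )


# ---------------------------------------------------------------------------
# Scaling + hierarchical clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringResult:
    scaled: pd.DataFrame
    gene_linkage: np.ndarray
    sample_linkage: np.ndarray
    gene_order: list[str]
    sample_order: list[str]
    constant_columns: list[str]


def _deterministic_leaf_order(linkage: np.ndarray, labels: list[str]) -> list[str]:
    """Leaf order with (merge height, then lexicographically smallest leaf)
    tie-breaking, independent of input row order."""
    n = len(labels)
    if n == 1:
        return list(labels)
    # node -> (height, min-label, leaves)
    nodes: dict[int, tuple[float, str, list[str]]] = {
        i: (0.0, labels[i], [labels[i]]) for i in range(n)
    }
    for k, (a, b, height, _) in enumerate(linkage):
        left = nodes.pop(int(a))
        right = nodes.pop(int(b))
        first, second = sorted((left, right), key=lambda nd: (nd[0], nd[1]))
        nodes[n + k] = (
            float(height),
            min(left[1], right[1]),
            first[2] + second[2],
        )
    (_, _, leaves), = nodes.values()
    return leaves


def scale_and_cluster(
    matrix: pd.DataFrame, genes_subset: list[str]
) -> ClusteringResult:
    """Per-sample z-scaling of a gene subset followed by agglomerative
    clustering of genes and samples (Euclidean distance, average linkage).

    Each sample column is centered and scaled to unit standard deviation
    within the subset; constant columns are left centered and reported.
    """
    subset = [g for g in genes_subset if g in matrix.index]
    if not subset:
        raise ValueError("gene subset is empty or absent from the matrix")
    sub = matrix.loc[subset].astype(float)
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1)
    constant = list(sub.columns[(sd == 0) | sd.isna()])
    if constant:
        warnings.warn(
            f"{len(constant)} constant sample column(s) left centered only",
            RuntimeWarning,
            stacklevel=2,
        )
    safe_sd = sd.replace(0, 1.0).fillna(1.0)
    scaled = sub.sub(mean, axis=1).div(safe_sd, axis=1)

    def _linkage(data: np.ndarray) -> np.ndarray:
        if data.shape[0] < 2:
            return np.empty((0, 4))
        return hierarchy.linkage(pdist(data, metric="euclidean"), method="average")

    gene_link = _linkage(scaled.to_numpy())
    sample_link = _linkage(scaled.to_numpy().T)
    gene_order = (
        _deterministic_leaf_order(gene_link, list(scaled.index))
        if len(scaled.index) > 1
        else list(scaled.index)
    )
    sample_order = (
        _deterministic_leaf_order(sample_link, list(scaled.columns))
        if len(scaled.columns) > 1
        else list(scaled.columns)
    )
    return ClusteringResult(
        scaled=scaled,
        gene_linkage=gene_link,
        sample_linkage=sample_link,
        gene_order=gene_order,
        sample_order=sample_order,
        constant_columns=constant,
    )


# ---------------------------------------------------------------------------
# External sign reference
# ---------------------------------------------------------------------------

_SIGN_TO_DIRECTION = {"+": "pos", "-": "neg", "−": "neg", "ns": "ns"}


def read_sign_reference(path: str | Path) -> pd.Series:
    """Read a reference TSV with columns ``set`` and ``sign`` (+/−/ns)."""
    tab = pd.read_csv(path, sep="\t", comment="#")
    if not {"set", "sign"} <= set(tab.columns):
        raise ValueError("reference table needs columns 'set' and 'sign'")
    signs = tab.set_index("set")["sign"].astype(str)
    bad = set(signs) - set(_SIGN_TO_DIRECTION)
    if bad:
        raise ValueError(f"unknown reference signs: {sorted(bad)}")
    return signs


def reference_sign_overlap(
    set_stats: pd.DataFrame, reference: pd.Series
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Direction concordance of model enrichment against a reference.

    Per reference set: the model estimate and direction, the reference sign,
    and a concordance flag. Reference-``ns`` sets and sets missing from the
    model results are excluded from the concordance denominator; sets where
    the model is ``ns`` but the reference is signed are counted separately.
    """
    records = []
    summary = {
        "concordant": 0,
        "discordant": 0,
        "reference_ns": 0,
        "model_ns": 0,
        "missing": 0,
    }
    for name, sign in reference.items():
        ref_dir = _SIGN_TO_DIRECTION[str(sign)]
        if name not in set_stats.index:
            records.append(
                {"set": name, "est": np.nan, "model_direction": "missing",
                 "reference_sign": sign, "status": "missing"}
            )
            summary["missing"] += 1
            continue
        est = float(set_stats.at[name, "est"])
        model_dir = str(set_stats.at[name, "direction"])
        if ref_dir == "ns":
            status = "reference_ns"
        elif model_dir == "ns":
            status = "model_ns"
        elif model_dir == ref_dir:
            status = "concordant"
        else:
            status = "discordant"
        summary[status] += 1
        records.append(
            {"set": name, "est": est, "model_direction": model_dir,
             "reference_sign": sign, "status": status}
        )
    return pd.DataFrame.from_records(records), summary


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_venn_table(venn: pd.DataFrame, path: str | Path, direction: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# Venn region counts, direction={direction}\n")
        venn.to_csv(fh, sep="\t", index=False)


def write_similarity(pair: SimilarityMatrixPair, outdir: str | Path,
                     prefix: str = "similarity") -> None:
    outdir = Path(outdir)
    for name, mat in (("pos", pair.pos), ("neg", pair.neg)):
        path = outdir / f"{prefix}_{name}.tsv"
        with open(path, "w") as fh:
            fh.write(
                "# row-wise overlap ratios: entry[a,b] = |a ∩ b| / |a|; "
                f"empty rows: {','.join(pair.empty_rows.get(name, [])) or 'none'}\n"
            )
            mat.to_csv(fh, sep="\t", index_label="model")
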