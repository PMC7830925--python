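"""Per-gene differential expression with empirical-Bayes moderated t-statistics.

Each study is a two-group knockout (KO) vs wild-type (WT) contrast on a
normalized log2 expression matrix. Per gene, an ordinary least-squares fit
gives the log2 fold change (KO − WT), the pooled residual variance and its
degrees of freedom. Residual variances are then shrunk toward a common prior
estimated by moment matching on the log variances (the standard moderated-t
construction), p-values come from a Student t with augmented degrees of
freedom, and multiplicity is controlled by Benjamini–Hochberg. A gene is
called differentially expressed when its FDR falls below ``alpha``; no fold
change cutoff is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

#: prior degrees of freedom used to represent "infinite" (no excess variance
#: in the observed residual variances beyond chi-square sampling noise).
D0_CAP = 1e6

WT_LABEL = "WT"
KO_LABEL = "KO"


@dataclass
class ExpressionStudy:
    """One model's log2 expression matrix plus its two-group design.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Genes in rows (unique index), samples in columns, log2 scale, no
        missing values.
    group : pandas.Series
        Per-sample genotype label, ``"WT"`` or ``"KO"``, indexed by the
        matrix columns.
    model_label : str
        Free-text name of the genetic model (e.g. ``"Glmp_KO"``).
    """

    matrix: pd.DataFrame
    group: pd.Series
    model_label: str = "model"

    def __post_init__(self) -> None:
        if self.matrix.index.has_duplicates:
            raise ValueError("gene identifiers must be unique")
        if self.matrix.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.group = pd.Series(self.group).reindex(self.matrix.columns)
        if self.group.isna().any():
            raise ValueError("every sample needs a group label")
        bad = set(self.group.unique()) - {WT_LABEL, KO_LABEL}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        for g in (WT_LABEL, KO_LABEL):
            if (self.group == g).sum() < 2:
                raise ValueError(f"group {g!r} has fewer than 2 samples")

    @property
    def genes(self) -> pd.Index:
        return self.matrix.index

    @property
    def samples(self) -> pd.Index:
        return self.matrix.columns

    @classmethod
    def from_tsv(
        cls,
        expression_path: str | Path,
        sample_sheet_path: str | Path,
        model_label: str | None = None,
    ) -> "ExpressionStudy":
        """Load a study from an expression TSV (first column ``gene_id``)
        and a sample sheet TSV with columns ``sample_id`` and ``genotype``."""
        mat = pd.read_csv(expression_path, sep="\t", index_col=0, comment="#")
        sheet = pd.read_csv(sample_sheet_path, sep="\t", comment="#")
        sheet = sheet.set_index("sample_id")
        group = sheet.loc[mat.columns, "genotype"]
        if model_label is None:
            model_label = (
                str(sheet["model"].iloc[0]) if "model" in sheet.columns else "model"
            )
        return cls(matrix=mat, group=group, model_label=model_label)


@dataclass
class GeneFit:
    """Per-gene OLS summaries for a two-group contrast.

    ``beta`` is mean(KO) − mean(WT), ``s2`` the pooled within-group variance
    on ``df`` = n_KO + n_WT − 2 degrees of freedom, and ``v`` the unscaled
    variance multiplier of ``beta`` (1/n_KO + 1/n_WT, identical for all
    genes under the common design).
    """

    genes: pd.Index
    beta: np.ndarray
    s2: np.ndarray
    df: float
    v: float


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled inverse-chi-square prior on the residual variances."""

    d0: float
    s0sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValueError("prior degrees of freedom d0 must be positive")
        if not self.s0sq > 0:
            raise ValueError("prior variance s0sq must be positive")


def fit_gene_models(study: ExpressionStudy) -> GeneFit:
    """Fit the KO−WT contrast gene by gene.

    Equivalent to per-gene OLS on a two-level factor; vectorized across the
    whole matrix.
    """
    ko = study.matrix.loc[:, (study.group == KO_LABEL).to_numpy()].to_numpy(float)
    wt = study.matrix.loc[:, (study.group == WT_LABEL).to_numpy()].to_numpy(float)
    n_ko, n_wt = ko.shape[1], wt.shape[1]
    beta = ko.mean(axis=1) - wt.mean(axis=1)
    ss = ko.var(axis=1, ddof=1) * (n_ko - 1) + wt.var(axis=1, ddof=1) * (n_wt - 1)
    df = n_ko + n_wt - 2
    s2 = ss / df
    v = 1.0 / n_ko + 1.0 / n_wt
    return GeneFit(genes=study.genes, beta=beta, s2=s2, df=float(df), v=float(v))


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def estimate_eb_prior(s2: np.ndarray, df: float) -> EBayesPrior:
    """Moment-match (d0, s0sq) on the log residual variances.

    Under the hierarchical model, s2 ~ s0sq · (chi²_df/df) · (d0/chi²_d0),
    so log s2 is a shifted log-F whose mean and variance have closed forms
    in digamma/trigamma. The excess of var(log s2) over trigamma(df/2)
    identifies d0; when that excess is non-positive the prior degrees of
    freedom are effectively infinite and we return the cap with the
    geometric-mean-based scale.
    """
    s2 = np.asarray(s2, dtype=float)
    if not df > 0:
        raise ValueError("residual degrees of freedom must be positive")
    pos = s2[s2 > 0]
    if s2.size == 0 or np.all(s2 == 0):
        raise ValueError(
            "all residual variances are zero; the data are degenerate "
            "(constant within groups for every gene)"
        )
    if pos.size < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    z = np.log(pos)
    e = z - float(special.digamma(df / 2.0)) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        if d0 >= D0_CAP:
            d0 = D0_CAP
        s0sq = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = D0_CAP
        s0sq = float(np.exp(emean))
    return EBayesPrior(d0=d0, s0sq=s0sq)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def moderated_stats(
    fit: GeneFit,
    prior: EBayesPrior | None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Moderated t, p, BH-FDR and direction per gene.

    The posterior variance is the df-weighted blend
    s2_post = (d0·s0sq + df·s2)/(d0 + df); the moderated t is
    beta/sqrt(s2_post·v) on df + d0 degrees of freedom. ``prior=None`` (or a
    zero-df prior, accepted as the plain-t escape hatch) reduces to the
    ordinary two-sample t. Direction is ``up``/``down`` only when
    fdr < alpha (strict).
    """
    if prior is None:
        d0, s0sq = 0.0, 0.0
    else:
        d0, s0sq = prior.d0, prior.s0sq
    beta, s2, df, v = fit.beta, fit.s2, fit.df, fit.v
    s2_post = (d0 * s0sq + df * s2) / (d0 + df)
    df_total = df + d0
    degenerate = s2_post == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = beta / np.sqrt(s2_post * v)
    # zero posterior variance: infinite t for any nonzero effect, t=0 otherwise
    t_mod = np.where(
        degenerate, np.where(beta > 0, np.inf, np.where(beta < 0, -np.inf, 0.0)), t_mod
    )
    if degenerate.any() and d0 == 0:
        warnings.warn(
            f"{int(degenerate.sum())} gene(s) with zero residual variance and "
            "no moderation; their p-values are set to 0 (nonzero effect) or 1",
            RuntimeWarning,
            stacklevel=2,
        )
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.where(np.isinf(t_mod), 0.0, p)
    p = np.where(degenerate & (beta == 0), 1.0, p)
    fdr = bh_adjust(p)
    direction = np.where(
        fdr < alpha, np.where(beta > 0, "up", "down"), "ns"
    )
    direction = np.where((fdr < alpha) & (beta == 0), "ns", direction)
    return pd.DataFrame(
        {
            "logFC": beta,
            "s2": s2,
            "df": df,
            "v": v,
            "t": t_mod,
            "p": p,
            "fdr": fdr,
            "direction": direction,
        },
        index=fit.genes,
    )


def run_differential_expression(
    study: ExpressionStudy, alpha: float = 0.05
) -> pd.DataFrame:
    """Full per-study pipeline: OLS fits → prior estimate → moderated stats."""
    fit = fit_gene_models(study)
    prior = estimate_eb_prior(fit.s2, fit.df)
    return moderated_stats(fit, prior, alpha=alpha)


def write_deg_table(table: pd.DataFrame, path: str | Path, model_label: str) -> None:
    out = table.loc[:, ["logFC", "t", "p", "fdr", "direction"]].copy()
    out.insert(0, "gene_id", out.index)
    with open(path, "w") as fh:
        fh.write(f"# differential expression, model={model_label}\n")
        out.to_csv(fh, sep="\t", index=False)
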