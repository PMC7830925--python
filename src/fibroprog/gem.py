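"""Constraint-based metabolic modeling and expression integration.

A metabolic model is a stoichiometric network with flux bounds, boolean
gene-protein-reaction (GPR) rules, subsystem labels and one objective
reaction. Differential expression is integrated by a two-condition MILP in
the style of Metabolic Adjustment by Differential Expression (MADE): binary
gene states are chosen for the wild-type and knockout conditions to maximize
the confidence-weighted agreement with the observed expression transitions
(+1 up, −1 down, 0 unchanged), subject to both condition models remaining
functional — GPR-consistent reaction states, steady-state mass balance, and
an objective flux of at least a fraction ``f`` of the unconstrained optimum.
Reactions are then classified up/down by comparing flux-variability
capacities between conditions, and subsystems are tested per direction with
the hypergeometric upper tail and Benjamini–Hochberg adjustment.

All LPs and the MILP run on scipy's HiGHS interfaces.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp
from scipy.stats import hypergeom

from fibroprog.diffexpr import bh_adjust

_NUM_TOL = 1e-9


class ModelValidationError(ValueError):
    """Raised when a metabolic model violates a structural invariant."""


class GPRSyntaxError(ValueError):
    """Raised for malformed gene-protein-reaction rule strings."""


# ---------------------------------------------------------------------------
# GPR rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPRNode:
    """Node of a parsed GPR expression tree.

    ``op`` is ``"gene"`` (leaf, ``gene`` set), ``"and"`` or ``"or"``
    (``children`` set).
    """

    op: str
    gene: str | None = None
    children: tuple["GPRNode", ...] = ()

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for child in self.children:
            out |= child.genes()
        return out


_TOKEN_RE = re.compile(r"\(|\)|\band\b|\bor\b|[^\s()]+", re.IGNORECASE)


def parse_gpr(rule: str | None) -> GPRNode | None:
    """Parse a boolean GPR string like ``"(gA and gB) or gC"``.

    Returns ``None`` for an empty rule (reaction not gene-associated).
    ``and`` binds tighter than ``or``; parentheses override.
    """
    if rule is None or not rule.strip():
        return None
    tokens = _TOKEN_RE.findall(rule)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GPRNode:
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GPRNode("or", children=tuple(terms))

    def parse_and() -> GPRNode:
        factors = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            factors.append(parse_atom())
        return (
            factors[0] if len(factors) == 1 else GPRNode("and", children=tuple(factors))
        )

    def parse_atom() -> GPRNode:
        tok = peek()
        if tok is None:
            raise GPRSyntaxError(f"unexpected end of GPR rule: {rule!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GPRSyntaxError(f"unbalanced parentheses in GPR rule: {rule!r}")
            take()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GPRSyntaxError(f"misplaced token {tok!r} in GPR rule: {rule!r}")
        return GPRNode("gene", gene=take())

    node = parse_or()
    if pos != len(tokens):
        raise GPRSyntaxError(f"trailing tokens in GPR rule: {rule!r}")
    return node


def eval_gpr(tree: GPRNode | None, gene_states: dict[str, int]) -> int:
    """Evaluate a GPR tree on binary gene states.

    AND is min, OR is max. An empty rule evaluates to 1 (always available);
    genes absent from ``gene_states`` are treated as active.
    """
    if tree is None:
        return 1
    if tree.op == "gene":
        return int(gene_states.get(tree.gene, 1))
    values = [eval_gpr(child, gene_states) for child in tree.children]
    return min(values) if tree.op == "and" else max(values)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    id: str
    name: str
    subsystem: str
    lb: float
    ub: float
    stoichiometry: dict[str, float]
    gpr: str = ""
    gpr_tree: GPRNode | None = field(default=None, repr=False)


@dataclass
class MetabolicModel:
    """Stoichiometric model with GPR rules, subsystems and one objective."""

    metabolites: list[dict]
    reactions: list[Reaction]
    objective: str

    def __post_init__(self) -> None:
        met_ids = [m["id"] for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError("duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError("duplicate reaction ids")
        met_set = set(met_ids)
        for rxn in self.reactions:
            if rxn.lb > rxn.ub:
                raise ModelValidationError(
                    f"reaction {rxn.id!r}: lb={rxn.lb} > ub={rxn.ub}"
                )
            unknown = set(rxn.stoichiometry) - met_set
            if unknown:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references unknown metabolites {sorted(unknown)}"
                )
            if not rxn.subsystem:
                raise ModelValidationError(f"reaction {rxn.id!r} has empty subsystem")
            if rxn.gpr_tree is None and rxn.gpr.strip():
                rxn.gpr_tree = parse_gpr(rxn.gpr)
        if self.objective not in set(rxn_ids):
            raise ModelValidationError(
                f"objective reaction {self.objective!r} not in model"
            )
        self._rxn_index = {r.id: i for i, r in enumerate(self.reactions)}
        self._met_index = {m: i for i, m in enumerate(met_ids)}

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            if rxn.gpr_tree is not None:
                for g in sorted(rxn.gpr_tree.genes()):
                    seen.setdefault(g)
        return list(seen)

    @property
    def subsystems(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions:
            seen.setdefault(rxn.subsystem)
        return list(seen)

    def stoichiometric_matrix(self) -> sparse.csr_matrix:
        rows, cols, data = [], [], []
        for j, rxn in enumerate(self.reactions):
            for met, coef in rxn.stoichiometry.items():
                rows.append(self._met_index[met])
                cols.append(j)
                data.append(float(coef))
        return sparse.csr_matrix(
            (data, (rows, cols)), shape=(len(self.metabolites), len(self.reactions))
        )

    def to_dict(self) -> dict:
        return {
            "metabolites": [dict(m) for m in self.metabolites],
            "reactions": [
                {
                    "id": r.id,
                    "name": r.name,
                    "subsystem": r.subsystem,
                    "lb": r.lb,
                    "ub": r.ub,
                    "gpr": r.gpr,
                    "metabolites": dict(r.stoichiometry),
                }
                for r in self.reactions
            ],
            "objective": self.objective,
        }

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)
            fh.write("\n")


def model_from_dict(payload: dict) -> MetabolicModel:
    try:
        metabolites = [
            {"id": m["id"], "compartment": m.get("compartment", "c")}
            for m in payload["metabolites"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                name=r.get("name", r["id"]),
                subsystem=r.get("subsystem", "Unassigned"),
                lb=float(r["lb"]),
                ub=float(r["ub"]),
                stoichiometry={k: float(v) for k, v in r["metabolites"].items()},
                gpr=r.get("gpr", ""),
            )
            for r in payload["reactions"]
        ]
        objective = payload["objective"]
    except (KeyError, TypeError) as exc:
        raise ModelValidationError(f"malformed model payload: {exc}") from exc
    return MetabolicModel(metabolites=metabolites, reactions=reactions, objective=objective)


def parse_model(path: str | Path) -> MetabolicModel:
    """Load and validate a model from the JSON dialect."""
    with open(path) as fh:
        payload = json.load(fh)
    return model_from_dict(payload)


# ---------------------------------------------------------------------------
# FBA / FVA
# ---------------------------------------------------------------------------

@dataclass
class FBAResult:
    status: str
    objective_value: float
    fluxes: dict[str, float]

    @property
    def ok(self) -> bool:
        return self.status == "optimal"


def _gated_bounds(
    model: MetabolicModel, active_states: dict[str, int] | None
) -> tuple[np.ndarray, np.ndarray]:
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    if active_states:
        for rid, state in active_states.items():
            if state == 0:
                j = model._rxn_index[rid]
                lb[j] = 0.0
                ub[j] = 0.0
    return lb, ub


def fba(
    model: MetabolicModel,
    active_states: dict[str, int] | None = None,
    extra_constraints: list[tuple[np.ndarray, float, float]] | None = None,
) -> FBAResult:
    """Maximize the objective flux: max c·v s.t. S·v = 0, lb' ≤ v ≤ ub'.

    ``active_states`` maps reaction id → {0,1}; inactive reactions are
    clamped to zero flux.
    """
    S = model.stoichiometric_matrix()
    lb, ub = _gated_bounds(model, active_states)
    c = np.zeros(len(model.reactions))
    c[model._rxn_index[model.objective]] = -1.0
    a_ub, b_ub = None, None
    if extra_constraints:
        a_ub = np.vstack([row for row, _, _ in extra_constraints])
        b_ub = np.array([hi for _, _, hi in extra_constraints])
    res = linprog(
        c,
        A_ub=a_ub,
        b_ub=b_ub,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=np.column_stack([lb, ub]),
        method="highs",
    )
    if res.status != 0:
        return FBAResult(status="infeasible" if res.status == 2 else "failed",
                         objective_value=float("nan"), fluxes={})
    fluxes = dict(zip(model.reaction_ids, res.x))
    return FBAResult(status="optimal", objective_value=float(-res.fun), fluxes=fluxes)


@dataclass
class FvaResult:
    """Per-reaction flux intervals under the functionality constraint."""

    intervals: pd.DataFrame  # columns lo, hi indexed by reaction id


def fva(
    model: MetabolicModel,
    active_states: dict[str, int] | None,
    f: float,
    reference_optimum: float,
) -> FvaResult:
    """Flux variability: per-reaction min/max flux with objective ≥ f·v*.

    Reactions whose state is 0 are reported as [0, 0] without solving.
    """
    S = model.stoichiometric_matrix()
    lb, ub = _gated_bounds(model, active_states)
    n = len(model.reactions)
    obj_j = model._rxn_index[model.objective]
    # objective flux >= f * v*  encoded as  -v_obj <= -f * v*
    a_ub = np.zeros((1, n))
    a_ub[0, obj_j] = -1.0
    b_ub = np.array([-(f * reference_optimum) + _NUM_TOL])
    bounds = np.column_stack([lb, ub])
    b_eq = np.zeros(S.shape[0])
    lo = np.zeros(n)
    hi = np.zeros(n)
    inactive = {
        model._rxn_index[rid]
        for rid, st in (active_states or {}).items()
        if st == 0
    }
    for j in range(n):
        if j in inactive:
            continue
        for sense, target in ((1.0, lo), (-1.0, hi)):
            c = np.zeros(n)
            c[j] = sense
            res = linprog(
                c, A_ub=a_ub, b_ub=b_ub, A_eq=S, b_eq=b_eq, bounds=bounds,
                method="highs",
            )
            if res.status != 0:
                raise RuntimeError(
                    f"FVA LP for reaction {model.reactions[j].id!r} "
                    f"returned status {res.status}"
                )
            target[j] = sense * res.fun
    table = pd.DataFrame({"lo": lo, "hi": hi}, index=model.reaction_ids)
    # clip tiny solver negatives crossing the interval
    swap = table["lo"] > table["hi"]
    if swap.any():
        mid = table.loc[swap].mean(axis=1)
        table.loc[swap, "lo"] = mid
        table.loc[swap, "hi"] = mid
    return FvaResult(intervals=table)


# ---------------------------------------------------------------------------
# Expression input
# ---------------------------------------------------------------------------

W_MAX = 10.0


def de_input_from_stats(
    stats_table: pd.DataFrame, alpha: float = 0.05, w_max: float = W_MAX
) -> pd.DataFrame:
    """Observed transitions and confidence weights from a DE table.

    d is the sign of logFC when fdr < alpha, else 0; w = −log10(p) capped
    at ``w_max``.
    """
    fdr = stats_table["fdr"].to_numpy(float)
    lfc = stats_table["logFC"].to_numpy(float)
    p = stats_table["p"].to_numpy(float)
    d = np.where(fdr < alpha, np.sign(lfc).astype(int), 0)
    with np.errstate(divide="ignore"):
        w = np.minimum(-np.log10(np.maximum(p, 0.0)), w_max)
    w = np.where(np.isfinite(w), w, w_max)
    return pd.DataFrame({"d": d.astype(int), "w": w}, index=stats_table.index)


# ---------------------------------------------------------------------------
# MADE MILP
# ---------------------------------------------------------------------------

CONDITIONS = ("WT", "KO")


@dataclass
class MadeSolution:
    gene_states: pd.DataFrame       # gene × condition, {0,1}
    reaction_states: pd.DataFrame   # reaction × condition, {0,1}
    objective_value: float          # achieved matched weight
    total_weight: float
    match_fraction: float
    matched: pd.Series              # per-gene bool
    solver_status: str
    genes_outside_model: int = 0


class _MilpBuilder:
    """Row-wise accumulator for a sparse MILP in scipy's canonical form."""

    def __init__(self) -> None:
        self.n_vars = 0
        self.lb: list[float] = []
        self.ub: list[float] = []
        self.integrality: list[int] = []
        self.rows: list[list[tuple[int, float]]] = []
        self.row_lo: list[float] = []
        self.row_hi: list[float] = []
        self.cost: dict[int, float] = {}

    def var(self, lo: float, hi: float, integer: bool) -> int:
        self.lb.append(lo)
        self.ub.append(hi)
        self.integrality.append(1 if integer else 0)
        self.n_vars += 1
        return self.n_vars - 1

    def add(self, terms: list[tuple[int, float]], lo: float, hi: float) -> None:
        self.rows.append(terms)
        self.row_lo.append(lo)
        self.row_hi.append(hi)

    def solve(self):
        r, c, d = [], [], []
        for i, terms in enumerate(self.rows):
            for j, coef in terms:
                r.append(i)
                c.append(j)
                d.append(coef)
        a = sparse.csr_matrix((d, (r, c)), shape=(len(self.rows), self.n_vars))
        cost = np.zeros(self.n_vars)
        for j, coef in self.cost.items():
            cost[j] = coef
        return milp(
            c=cost,
            constraints=LinearConstraint(a, np.array(self.row_lo), np.array(self.row_hi)),
            integrality=np.array(self.integrality),
            bounds=Bounds(np.array(self.lb), np.array(self.ub)),
        )


def _linearize_gpr(builder: _MilpBuilder, tree: GPRNode, gene_var: dict[str, int]) -> int:
    """Emit MILP constraints tying an aux binary to the boolean value of the
    tree; returns the variable index holding the tree's value."""
    if tree.op == "gene":
        return gene_var[tree.gene]
    child_vars = [_linearize_gpr(builder, ch, gene_var) for ch in tree.children]
    y = builder.var(0, 1, integer=True)
    k = len(child_vars)
    if tree.op == "and":
        for cv in child_vars:  # y <= c_i
            builder.add([(y, 1.0), (cv, -1.0)], -np.inf, 0.0)
        # y >= sum(c) - (k-1)
        builder.add([(y, 1.0)] + [(cv, -1.0) for cv in child_vars], -(k - 1), np.inf)
    else:  # or
        for cv in child_vars:  # y >= c_i
            builder.add([(y, 1.0), (cv, -1.0)], 0.0, np.inf)
        # y <= sum(c)
        builder.add([(y, 1.0)] + [(cv, -1.0) for cv in child_vars], -np.inf, 0.0)
    return y


def made_integrate(
    model: MetabolicModel,
    de: pd.DataFrame,
    f: float = 0.3,
) -> MadeSolution:
    """Fit binary WT/KO gene states to the observed expression transitions.

    ``de`` is indexed by gene with columns ``d`` (+1/−1/0) and ``w`` (≥0).
    Genes in the model but absent from ``de`` are treated as d=0, w=0.
    Genes in ``de`` but not in any GPR cannot constrain the network and are
    ignored (their count is reported). Both condition models must achieve an
    objective flux of at least ``f`` times the all-active FBA optimum.
    """
    ref = fba(model)
    if not ref.ok or ref.objective_value <= 0:
        raise RuntimeError(
            "reference model must be feasible with positive objective "
            f"(status={ref.status}, objective={ref.objective_value})"
        )
    vstar = ref.objective_value

    model_genes = model.genes
    de = de.copy()
    outside = int((~de.index.isin(model_genes)).sum())
    d = {g: int(de.at[g, "d"]) if g in de.index else 0 for g in model_genes}
    w = {g: float(de.at[g, "w"]) if g in de.index else 0.0 for g in model_genes}

    builder = _MilpBuilder()
    n_rxn = len(model.reactions)
    obj_j = model._rxn_index[model.objective]
    gene_vars: dict[str, dict[str, int]] = {}
    for cond in CONDITIONS:
        gene_vars[cond] = {g: builder.var(0, 1, integer=True) for g in model_genes}

    state_vars: dict[str, dict[str, int]] = {c: {} for c in CONDITIONS}
    for cond in CONDITIONS:
        # flux variables with GPR-gated bounds
        v_idx = []
        for rxn in model.reactions:
            v = builder.var(min(rxn.lb, 0.0), max(rxn.ub, 0.0), integer=False)
            v_idx.append(v)
            if rxn.gpr_tree is not None:
                s = _linearize_gpr(builder, rxn.gpr_tree, gene_vars[cond])
                state_vars[cond][rxn.id] = s
                # v <= ub * s ; v >= lb * s
                builder.add([(v, 1.0), (s, -rxn.ub)], -np.inf, 0.0)
                builder.add([(v, 1.0), (s, -rxn.lb)], 0.0, np.inf)
            else:
                builder.add([(v, 1.0)], rxn.lb, rxn.ub)
        # mass balance S v = 0
        S = model.stoichiometric_matrix().tocoo()
        per_row: dict[int, list[tuple[int, float]]] = {}
        for i, j, coef in zip(S.row, S.col, S.data):
            per_row.setdefault(i, []).append((v_idx[j], float(coef)))
        for terms in per_row.values():
            builder.add(terms, 0.0, 0.0)
        # functionality: objective flux >= f * v*
        builder.add([(v_idx[obj_j], 1.0)], f * vstar - _NUM_TOL, np.inf)

    # match variables
    match_vars: dict[str, int] = {}
    for g in model_genes:
        m = builder.var(0, 1, integer=True)
        match_vars[g] = m
        awt, ako = gene_vars["WT"][g], gene_vars["KO"][g]
        if d[g] == 1:
            builder.add([(m, 1.0), (ako, -1.0)], -np.inf, 0.0)
            builder.add([(m, 1.0), (awt, 1.0)], -np.inf, 1.0)
        elif d[g] == -1:
            builder.add([(m, 1.0), (awt, -1.0)], -np.inf, 0.0)
            builder.add([(m, 1.0), (ako, 1.0)], -np.inf, 1.0)
        else:
            builder.add([(m, 1.0), (ako, -1.0), (awt, 1.0)], -np.inf, 1.0)
            builder.add([(m, 1.0), (ako, 1.0), (awt, -1.0)], -np.inf, 1.0)
        builder.cost[m] = -w[g]  # milp minimizes

    res = builder.solve()
    if res.status != 0 or res.x is None:
        status = {1: "iteration_limit", 2: "infeasible", 3: "unbounded"}.get(
            res.status, "failed"
        )
        raise RuntimeError(
            f"MADE MILP did not reach proven optimality (status={status}); "
            "consider lowering the functionality fraction f"
        )

    # Tie-break among match-optimal solutions: keep as many gene states
    # active as possible, so the networks deviate from the fully active
    # reference only where the expression evidence demands it.
    best = -res.fun  # matched weight at the optimum
    builder.add(
        [(m, w[g]) for g, m in match_vars.items()],
        best - 1e-7 * max(1.0, abs(best)),
        np.inf,
    )
    builder.cost = {}
    for cond in CONDITIONS:
        for var in gene_vars[cond].values():
            builder.cost[var] = -1.0
    res = builder.solve()
    if res.status != 0 or res.x is None:
        raise RuntimeError("MADE tie-breaking MILP failed unexpectedly")

    x = res.x
    gene_states = pd.DataFrame(
        {
            cond: [int(round(x[gene_vars[cond][g]])) for g in model_genes]
            for cond in CONDITIONS
        },
        index=model_genes,
    )
    reaction_states = pd.DataFrame(
        {
            cond: [
                eval_gpr(rxn.gpr_tree, dict(gene_states[cond]))
                for rxn in model.reactions
            ]
            for cond in CONDITIONS
        },
        index=model.reaction_ids,
    )
    # consistency: the MILP's own state binaries must agree with the GPR
    for cond in CONDITIONS:
        for rid, s in state_vars[cond].items():
            if int(round(x[s])) != reaction_states.at[rid, cond]:
                raise RuntimeError(
                    f"GPR linearization inconsistency for {rid!r} ({cond})"
                )

    matched = {}
    for g in model_genes:
        awt, ako = gene_states.at[g, "WT"], gene_states.at[g, "KO"]
        if d[g] == 1:
            matched[g] = ako - awt == 1
        elif d[g] == -1:
            matched[g] = ako - awt == -1
        else:
            matched[g] = ako == awt
    matched = pd.Series(matched, index=model_genes)
    objective_value = float(sum(w[g] for g in model_genes if matched[g]))
    total = float(sum(w.values()))
    return MadeSolution(
        gene_states=gene_states,
        reaction_states=reaction_states,
        objective_value=objective_value,
        total_weight=total,
        match_fraction=objective_value / total if total > 0 else 1.0,
        matched=matched,
        solver_status="optimal",
        genes_outside_model=outside,
    )


# ---------------------------------------------------------------------------
# Reaction classification and subsystem enrichment
# ---------------------------------------------------------------------------

EPS_CAPACITY = 1e-6


def classify_reactions(
    fva_wt: FvaResult,
    fva_ko: FvaResult,
    states: pd.DataFrame,
    eps: float = EPS_CAPACITY,
) -> pd.Series:
    """Label each reaction up/down/unchanged between conditions.

    Capacity is max(|lo|, |hi|) of the flux interval; a reaction is up when
    the KO capacity exceeds the WT capacity by more than ``eps`` and down in
    the opposite case. Reactions switched off by the gene states (WT 1 →
    KO 0) are down — and switched on are up — regardless of capacity.
    """
    idx = fva_wt.intervals.index
    if not idx.equals(fva_ko.intervals.index):
        raise ValueError("FVA results cover different reaction lists")
    m_wt = fva_wt.intervals.abs().max(axis=1)
    m_ko = fva_ko.intervals.abs().max(axis=1)
    label = pd.Series("unchanged", index=idx, dtype=object)
    label[m_ko - m_wt > eps] = "up"
    label[m_wt - m_ko > eps] = "down"
    on_wt = states["WT"].reindex(idx).fillna(1).astype(int)
    on_ko = states["KO"].reindex(idx).fillna(1).astype(int)
    label[(on_wt == 1) & (on_ko == 0)] = "down"
    label[(on_wt == 0) & (on_ko == 1)] = "up"
    return label


def hypergeom_upper_tail(k: int, n_total: int, big_k: int, n_draw: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N=n_total, K=big_k, n=n_draw)."""
    return float(hypergeom.sf(k - 1, n_total, big_k, n_draw))


def subsystem_enrichment(
    classification: pd.Series,
    model: MetabolicModel,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric subsystem test, per direction, BH within direction.

    For each subsystem (K of N model reactions) and direction with n
    classified reactions of which k fall in the subsystem, the p-value is
    the upper tail P(X ≥ k), X ~ Hypergeometric(N, K, n).
    """
    subsys = pd.Series(
        {r.id: r.subsystem for r in model.reactions}, name="subsystem"
    )
    n_total = len(model.reactions)
    records = []
    for direction in ("up", "down"):
        in_dir = classification == direction
        n = int(in_dir.sum())
        for name in model.subsystems:
            members = subsys == name
            big_k = int(members.sum())
            k = int((in_dir & members.reindex(in_dir.index).fillna(False)).sum())
            p = 1.0 if n == 0 else hypergeom_upper_tail(k, n_total, big_k, n)
            records.append(
                {
                    "subsystem": name,
                    "direction": direction,
                    "K": big_k,
                    "N": n_total,
                    "n": n,
                    "k": k,
                    "p": p,
                }
            )
    table = pd.DataFrame.from_records(records)
    table["fdr"] = 1.0
    for direction in ("up", "down"):
        mask = table["direction"] == direction
        table.loc[mask, "fdr"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    table["significant"] = table["fdr"] < alpha
    return table


@dataclass
class GemAnalysis:
    solution: MadeSolution
    fva_wt: FvaResult
    fva_ko: FvaResult
    classification: pd.Series
    subsystems: pd.DataFrame
    reference_optimum: float


def run_gem_integration(
    model: MetabolicModel,
    stats_table: pd.DataFrame,
    alpha: float = 0.05,
    f: float = 0.3,
    w_max: float = W_MAX,
    eps: float = EPS_CAPACITY,
) -> GemAnalysis:
    """DE table → MADE states → per-condition FVA → classes → subsystems."""
    de = de_input_from_stats(stats_table, alpha=alpha, w_max=w_max)
    solution = made_integrate(model, de, f=f)
    ref = fba(model)
    results = {}
    for cond in CONDITIONS:
        states = dict(solution.reaction_states[cond])
        results[cond] = fva(model, states, f=f, reference_optimum=ref.objective_value)
    classes = classify_reactions(
        results["WT"], results["KO"], solution.reaction_states, eps=eps
    )
    subsystems = subsystem_enrichment(classes, model, alpha=alpha)
    return GemAnalysis(
        solution=solution,
        fva_wt=results["WT"],
        fva_ko=results["KO"],
        classification=classes,
        subsystems=subsystems,
        reference_optimum=ref.objective_value,
    )


def write_gem_tables(
    analysis: GemAnalysis, model: MetabolicModel, outdir: str | Path, model_label: str
) -> tuple[Path, Path]:
    outdir = Path(outdir)
    rxn = pd.DataFrame(
        {
            "reaction": model.reaction_ids,
            "subsystem": [r.subsystem for r in model.reactions],
            "state_WT": analysis.solution.reaction_states["WT"].to_numpy(),
            "state_KO": analysis.solution.reaction_states["KO"].to_numpy(),
            "lo_WT": analysis.fva_wt.intervals["lo"].to_numpy(),
            "hi_WT": analysis.fva_wt.intervals["hi"].to_numpy(),
            "lo_KO": analysis.fva_ko.intervals["lo"].to_numpy(),
            "hi_KO": analysis.fva_ko.intervals["hi"].to_numpy(),
            "class": analysis.classification.to_numpy(),
        }
    )
    rxn_path = outdir / f"gem_reactions_{model_label}.tsv"
    with open(rxn_path, "w") as fh:
        fh.write(f"# GEM reaction states and FVA intervals, model={model_label}\n")
        rxn.to_csv(fh, sep="\t", index=False)
    sub_path = outdir / f"gem_subsystems_{model_label}.tsv"
    with open(sub_path, "w") as fh:
        fh.write(f"# GEM subsystem enrichment, model={model_label}\n")
        analysis.subsystems.to_csv(fh, sep="\t", index=False)
    return rxn_path, sub_path
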