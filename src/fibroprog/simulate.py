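"""Synthetic multi-model knockout studies with planted ground truth.

The generator emulates the statistical structure of a panel of independent
KO-vs-WT liver microarray studies: each model shares a set of commonly
perturbed genes (predominantly upregulated, mirroring the asymmetry seen in
fibrotic livers), carries its own model-specific perturbed genes, and has
gene-wise variances drawn from a scaled inverse-chi-square prior — exactly
the hierarchical model the moderated-t machinery downstream assumes.
Expression is simulated directly on the normalized log2 scale; array-level
artifacts (probe effects, batch, normalization) are not emulated.

Alongside the expression studies the module generates gene-set collections
with planted positively-enriched sets, and ships a hand-curated toy
metabolic network whose fatty-acid beta-oxidation genes are renamed to the
planted commonly-downregulated genes, so the metabolic-integration stage has
a recoverable signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from fibroprog.diffexpr import ExpressionStudy
from fibroprog.enrichment import write_gmt
from fibroprog.gem import MetabolicModel, Reaction

#: subsystem of the toy network whose genes are the planted down genes
DESIGNATED_SUBSYSTEM = "Fatty acid beta-oxidation"


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic panel.

    Defaults mirror the emulated design: five KO models, four samples per
    group on ~2000 genes, a shared program of 50 commonly upregulated and 5
    commonly downregulated genes at one log2 unit, and residual variances
    from a scaled inverse-chi-square(d0=4, s0sq=0.04) prior.
    """

    n_models: int = 5
    genes: int = 2000
    samples_per_group: int = 4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.5
    prior_df: float = 4.0           # d0
    prior_var: float = 0.04         # s0sq, log2^2
    common_up: int = 50
    common_down: int = 5
    specific_per_model: int = 30
    effect_size: float = 1.0        # log2 units
    planted_set_count: int = 5
    planted_set_size: int = 20
    planted_set_fraction: float = 0.5
    decoy_set_count: int = 40
    decoy_set_size: tuple[int, int] = (10, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_models": self.n_models,
            "genes": self.genes,
            "samples_per_group": self.samples_per_group,
            "planted_set_count": self.planted_set_count,
            "planted_set_size": self.planted_set_size,
            "decoy_set_count": self.decoy_set_count,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.common_up < 0 or self.common_down < 0 or self.specific_per_model < 0:
            raise ValueError("planted gene counts cannot be negative")
        planted = self.common_up + self.common_down + self.n_models * self.specific_per_model
        if planted > self.genes:
            raise ValueError(
                f"planted genes ({planted}) exceed the gene universe ({self.genes})"
            )
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if not (self.prior_df > 0 and self.prior_var > 0):
            raise ValueError("variance prior parameters must be positive")
        if not 0 < self.planted_set_fraction <= 1:
            raise ValueError("planted_set_fraction must be in (0, 1]")
        lo, hi = self.decoy_set_size
        if not (2 <= lo <= hi):
            raise ValueError("decoy_set_size must satisfy 2 <= lo <= hi")
        if hi > self.genes or self.planted_set_size > self.genes:
            raise ValueError("requested set size exceeds the gene universe")


@dataclass
class GroundTruth:
    """Planted structure behind one simulated panel."""

    genes: list[str]
    common_up: list[str]
    common_down: list[str]
    model_up: dict[str, list[str]]
    model_down: dict[str, list[str]]
    enriched_sets: dict[str, str] = field(default_factory=dict)   # name -> pos/neg
    perturbed_subsystems: dict[str, str] = field(default_factory=dict)  # name -> up/down

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)
            fh.write("\n")


def _model_names(n: int) -> list[str]:
    return [f"model{i + 1}" for i in range(n)]


def sample_variances(
    rng: np.random.Generator, size: int, d0: float, s0sq: float
) -> np.ndarray:
    """Draw gene variances from the scaled inverse-chi-square prior
    s0sq·d0/chi²_{d0}."""
    return s0sq * d0 / rng.chisquare(d0, size=size)


def simulate_studies(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Generate one KO-vs-WT study per model with planted effects.

    Per model, gene g in sample j reads μ_g + δ·sign_g·1[g planted, j in KO]
    + ε with ε ~ N(0, σ_g²) and σ_g² drawn from the inverse-chi-square
    prior (shared across that gene's samples within the study). Model
    baselines and variances are drawn independently per model, emulating
    independent studies on different platforms. Deterministic under the
    config seed.
    """
    rng = np.random.default_rng([config.seed, 0])
    G, n = config.genes, config.samples_per_group
    gene_ids = [f"G{i:05d}" for i in range(G)]
    names = _model_names(config.n_models)

    perm = rng.permutation(G)
    cu, cd, spm = config.common_up, config.common_down, config.specific_per_model
    common_up = [gene_ids[i] for i in perm[:cu]]
    common_down = [gene_ids[i] for i in perm[cu : cu + cd]]
    model_up: dict[str, list[str]] = {}
    model_down: dict[str, list[str]] = {}
    offset = cu + cd
    for name in names:
        block = [gene_ids[i] for i in perm[offset : offset + spm]]
        offset += spm
        half = len(block) // 2
        model_up[name] = sorted(common_up + block[:half])
        model_down[name] = sorted(common_down + block[half:])

    truth = GroundTruth(
        genes=gene_ids,
        common_up=sorted(common_up),
        common_down=sorted(common_down),
        model_up=model_up,
        model_down=model_down,
    )

    studies = []
    for name in names:
        mu = rng.normal(config.baseline_mean, config.baseline_sd, size=G)
        sigma2 = sample_variances(rng, G, config.prior_df, config.prior_var)
        noise = rng.normal(0.0, np.sqrt(sigma2)[:, None], size=(G, 2 * n))
        mat = mu[:, None] + noise
        delta = np.zeros(G)
        up_idx = [int(g[1:]) for g in model_up[name]]
        down_idx = [int(g[1:]) for g in model_down[name]]
        delta[up_idx] = config.effect_size
        delta[down_idx] = -config.effect_size
        mat[:, n:] += delta[:, None]
        samples = [f"{name}_WT_{j + 1}" for j in range(n)] + [
            f"{name}_KO_{j + 1}" for j in range(n)
        ]
        frame = pd.DataFrame(mat, index=gene_ids, columns=samples)
        group = pd.Series(["WT"] * n + ["KO"] * n, index=samples)
        studies.append(ExpressionStudy(matrix=frame, group=group, model_label=name))
    return studies, truth


def simulate_gene_sets(
    config: SimulationConfig, truth: GroundTruth
) -> dict[str, list[str]]:
    """Planted positively-enriched sets plus uniform decoys (raw, unfiltered).

    The commonly upregulated genes are spread over ``planted_set_count``
    sets; each planted set holds ``planted_set_fraction`` of its members
    from that pool and is filled up with random non-planted genes. Decoy
    sets are drawn uniformly from the whole gene universe. Updates
    ``truth.enriched_sets`` with the expected direction of planted sets.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes = truth.genes
    planted_pool = list(truth.common_up)
    perturbed = set(truth.common_up) | set(truth.common_down)
    for name in truth.model_up:
        perturbed |= set(truth.model_up[name]) | set(truth.model_down[name])
    fillers_pool = [g for g in genes if g not in perturbed]

    per_set = max(1, int(round(config.planted_set_fraction * config.planted_set_size)))
    sets: dict[str, list[str]] = {}
    for i in range(config.planted_set_count):
        chunk = planted_pool[i * per_set : (i + 1) * per_set]
        if not chunk:  # more sets than planted genes: recycle from the pool
            chunk = list(
                rng.choice(planted_pool, size=min(per_set, len(planted_pool)), replace=False)
            )
        n_fill = config.planted_set_size - len(chunk)
        fill = list(rng.choice(fillers_pool, size=n_fill, replace=False))
        name = f"PLANTED_SET_{i + 1}"
        sets[name] = chunk + fill
        truth.enriched_sets[name] = "pos"

    lo, hi = config.decoy_set_size
    for i in range(config.decoy_set_count):
        size = int(rng.integers(lo, hi + 1))
        sets[f"DECOY_SET_{i + 1}"] = list(rng.choice(genes, size=size, replace=False))
    return sets


def _toy_reactions(gene_map: dict[str, str]) -> list[Reaction]:
    """The fixed toy network; ``gene_map`` renames the placeholder gene ids."""

    def g(name: str) -> str:
        return gene_map.get(name, name)

    spec = [
        # id, name, subsystem, lb, ub, stoich, gpr
        ("EX_glc", "glucose uptake", "Exchange", 0, 10, {"glc_c": 1}, ""),
        ("EX_fa", "fatty acid uptake", "Exchange", 0, 5, {"fa_c": 1}, ""),
        ("EX_glu", "glutamate uptake", "Exchange", 0, 4, {"glu_c": 1}, ""),
        ("HEX", "hexokinase", "Glycolysis", 0, 10,
         {"glc_c": -1, "g6p_c": 1}, g("hk")),
        ("PYK", "lower glycolysis (lumped)", "Glycolysis", 0, 10,
         {"g6p_c": -1, "pyr_c": 2}, f"{g('gpi')} and {g('pfk')}"),
        ("PDH", "pyruvate dehydrogenase", "Pyruvate metabolism", 0, 12,
         {"pyr_c": -1, "accoa_c": 1}, g("pdh")),
        ("PC", "pyruvate carboxylase", "Pyruvate metabolism", 0, 6,
         {"pyr_c": -1, "oaa_c": 1}, g("pc")),
        ("LDH", "lactate dehydrogenase", "Pyruvate metabolism", 0, 4,
         {"pyr_c": -1, "lac_c": 1}, g("ldha")),
        ("EX_lac", "lactate export", "Transport", 0, 4, {"lac_c": -1}, ""),
        ("FATP", "fatty acid mitochondrial import", DESIGNATED_SUBSYSTEM, 0, 5,
         {"fa_c": -1, "fa_m": 1}, g("dn1")),
        ("FACOAL", "fatty acyl-CoA ligase", DESIGNATED_SUBSYSTEM, 0, 5,
         {"fa_m": -1, "facoa_m": 1}, g("dn2")),
        ("CPT1", "carnitine shuttle", DESIGNATED_SUBSYSTEM, 0, 5,
         {"facoa_m": -1, "facrn_m": 1}, g("dn3")),
        ("BOX1", "beta-oxidation (long chain)", DESIGNATED_SUBSYSTEM, 0, 5,
         {"facrn_m": -1, "pcoa_m": 1}, f"{g('dn4')} and {g('dn5')}"),
        ("BOX2", "beta-oxidation (short chain)", DESIGNATED_SUBSYSTEM, 0, 5,
         {"pcoa_m": -1, "accoa_c": 2}, f"{g('dn4')} or {g('dn5')}"),
        ("GLUDH", "glutamate dehydrogenase", "Amino acid metabolism", 0, 4,
         {"glu_c": -1, "akg_c": 1}, g("glud")),
        ("ALT", "alanine transaminase", "Amino acid metabolism", 0, 3,
         {"pyr_c": -1, "glu_c": -1, "ala_c": 1, "akg_c": 1}, g("gpt")),
        ("ALA_EXP", "alanine export", "Transport", 0, 3, {"ala_c": -1}, ""),
        ("CS", "citrate synthase", "TCA cycle", 0, 2,
         {"accoa_c": -1, "oaa_c": -1, "cit_c": 1}, g("cs")),
        ("IDH", "isocitrate dehydrogenase (lumped)", "TCA cycle", 0, 2,
         {"cit_c": -1, "akg_c": 1}, g("idh")),
        ("AKGDH", "akg to oxaloacetate (lumped)", "TCA cycle", 0, 6,
         {"akg_c": -1, "oaa_c": 1}, g("ogdh")),
        ("GS", "glycogen synthase", "Glycogen metabolism", 0, 2,
         {"g6p_c": -1, "glyc_c": 1}, g("gys")),
        ("GP", "glycogen phosphorylase", "Glycogen metabolism", 0, 2,
         {"glyc_c": -1, "g6p_c": 1}, g("pygl")),
        ("PPP", "pentose phosphate (lumped)", "Pentose phosphate pathway", 0, 2,
         {"g6p_c": -1, "r5p_c": 1}, g("g6pd")),
        ("DM_r5p", "ribose demand", "Transport", 0, 2, {"r5p_c": -1}, ""),
        ("NUCS", "nucleotide synthesis (lumped)", "Nucleotide metabolism", 0, 2,
         {"r5p_c": -1, "nuc_c": 1}, g("prps")),
        ("EX_nuc", "nucleotide demand", "Nucleotide metabolism", 0, 2,
         {"nuc_c": -1}, ""),
        ("BIOMASS", "biomass assembly", "Biomass", 0, 1000,
         {"accoa_c": -2, "oaa_c": -1, "bm_c": 1}, ""),
        ("EX_bm", "biomass sink", "Biomass", 0, 1000, {"bm_c": -1}, ""),
    ]
    return [
        Reaction(id=i, name=nm, subsystem=sub, lb=float(lb), ub=float(ub),
                 stoichiometry=dict(st), gpr=gpr)
        for i, nm, sub, lb, ub, st, gpr in spec
    ]


_TOY_METS = [
    ("glc_c", "c"), ("g6p_c", "c"), ("pyr_c", "c"), ("accoa_c", "c"),
    ("oaa_c", "c"), ("cit_c", "c"), ("akg_c", "c"), ("glu_c", "c"),
    ("ala_c", "c"), ("lac_c", "c"), ("fa_c", "c"), ("fa_m", "m"), ("facoa_m", "m"),
    ("facrn_m", "m"), ("pcoa_m", "m"), ("glyc_c", "c"), ("r5p_c", "c"),
    ("nuc_c", "c"), ("bm_c", "c"),
]

#: placeholder ids of the housekeeping enzymes in the fixed network
_HOUSEKEEPING = [
    "hk", "gpi", "pfk", "pdh", "pc", "glud", "gpt", "cs", "idh", "ogdh",
    "gys", "pygl", "g6pd", "prps", "ldha",
]


def toy_metabolic_model(truth: GroundTruth | None = None) -> MetabolicModel:
    """The shipped toy liver-like network (fixed topology, 19 metabolites,
    28 reactions, 11 subsystems, biomass objective).

    When ``truth`` is given, the five beta-oxidation genes are renamed to
    the planted commonly-downregulated genes and the housekeeping genes to
    unperturbed genes from the simulated universe, so the network's GPR
    layer connects to the expression data. ``truth.perturbed_subsystems`` is
    updated to mark the beta-oxidation subsystem as expected-down.
    """
    gene_map: dict[str, str] = {}
    if truth is not None:
        down = list(truth.common_down)
        if not down:
            raise ValueError("ground truth has no commonly downregulated genes")
        for i in range(5):
            gene_map[f"dn{i + 1}"] = down[i % len(down)]
        perturbed = set(truth.common_up) | set(truth.common_down)
        for name in truth.model_up:
            perturbed |= set(truth.model_up[name]) | set(truth.model_down[name])
        stable = [g for g in reversed(truth.genes) if g not in perturbed]
        for placeholder, gid in zip(_HOUSEKEEPING, stable):
            gene_map[placeholder] = gid
        truth.perturbed_subsystems[DESIGNATED_SUBSYSTEM] = "down"
    model = MetabolicModel(
        metabolites=[{"id": m, "compartment": c} for m, c in _TOY_METS],
        reactions=_toy_reactions(gene_map),
        objective="EX_bm",
    )
    return model


def random_toy_network(
    rng: np.random.Generator,
    n_genes: int = 6,
    n_paths: int = 3,
    depth: int = 2,
) -> MetabolicModel:
    """Small random feasible networks for MILP oracle fuzzing (not part of
    the study conditions): parallel substrate→product chains converging on
    one objective metabolite, with random AND/OR rules over a small gene
    pool. FBA optimum is positive with all genes active by construction.
    """
    genes = [f"rg{i}" for i in range(n_genes)]
    mets: list[tuple[str, str]] = [("obj_m", "c")]
    reactions: list[Reaction] = []

    def random_rule() -> str:
        k = int(rng.integers(1, 4))
        chosen = list(rng.choice(genes, size=min(k, n_genes), replace=False))
        if len(chosen) == 1:
            return chosen[0]
        op = " and " if rng.random() < 0.5 else " or "
        rule = op.join(chosen)
        if len(chosen) == 3 and rng.random() < 0.5:
            other = " or " if op == " and " else " and "
            rule = f"({chosen[0]}{op}{chosen[1]}){other}{chosen[2]}"
        return rule

    for p in range(n_paths):
        prev = f"s{p}_0"
        mets.append((prev, "c"))
        cap = float(rng.integers(2, 8))
        reactions.append(
            Reaction(id=f"EX_{p}", name=f"uptake {p}", subsystem="Exchange",
                     lb=0.0, ub=cap, stoichiometry={prev: 1.0}, gpr="")
        )
        for step in range(depth):
            nxt = f"s{p}_{step + 1}" if step < depth - 1 else "obj_m"
            if nxt != "obj_m":
                mets.append((nxt, "c"))
            rule = random_rule() if rng.random() < 0.85 else ""
            reactions.append(
                Reaction(
                    id=f"R_{p}_{step}", name=f"step {p}.{step}",
                    subsystem=f"Pathway {p}", lb=0.0,
                    ub=float(rng.integers(2, 10)),
                    stoichiometry={prev: -1.0, nxt: 1.0}, gpr=rule,
                )
            )
            prev = nxt
    reactions.append(
        Reaction(id="OBJ", name="objective sink", subsystem="Objective",
                 lb=0.0, ub=1000.0, stoichiometry={"obj_m": -1.0}, gpr="")
    )
    return MetabolicModel(
        metabolites=[{"id": m, "compartment": c} for m, c in mets],
        reactions=reactions,
        objective="OBJ",
    )


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_panel(
    studies: list[ExpressionStudy],
    truth: GroundTruth,
    raw_sets: dict[str, list[str]],
    model: MetabolicModel,
    outdir: str | Path,
    sexes: dict[str, str] | None = None,
) -> None:
    """Write expression TSVs, sample sheets, GMT, model JSON and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for study in studies:
        label = study.model_label
        expr = study.matrix.copy()
        expr.insert(0, "gene_id", expr.index)
        expr.to_csv(outdir / f"expression_{label}.tsv", sep="\t", index=False)
        sex = (sexes or {}).get(label, "M")
        sheet = pd.DataFrame(
            {
                "sample_id": study.samples,
                "model": label,
                "genotype": study.group.to_numpy(),
                "sex": sex,
            }
        )
        sheet.to_csv(outdir / f"samples_{label}.tsv", sep="\t", index=False)
    write_gmt(raw_sets, outdir / "gene_sets.gmt")
    model.to_json(outdir / "toy_gem.json")
    truth.to_json(outdir / "ground_truth.json")
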