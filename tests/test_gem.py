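"""Tests for the constraint-based modeling stage.

The FBA/FVA implementations run on scipy's HiGHS; cobrapy (GLPK backend)
serves as the independent oracle where a second solver is warranted.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fibroprog.gem import (
    FvaResult,
    GPRSyntaxError,
    MetabolicModel,
    ModelValidationError,
    Reaction,
    classify_reactions,
    de_input_from_stats,
    eval_gpr,
    fba,
    fva,
    made_integrate,
    model_from_dict,
    parse_gpr,
    parse_model,
    subsystem_enrichment,
)
from fibroprog.simulate import toy_metabolic_model


def _chain_model(ubs=(10, 5, 8), gprs=("", "", "")):
    """source -> A -> B -> sink with the given capacities."""
    mets = [{"id": "A", "compartment": "c"}, {"id": "B", "compartment": "c"}]
    reactions = [
        Reaction("R1", "uptake", "Exchange", 0, ubs[0], {"A": 1}, gprs[0]),
        Reaction("R2", "convert", "Core", 0, ubs[1], {"A": -1, "B": 1}, gprs[1]),
        Reaction("R3", "sink", "Exchange", 0, ubs[2], {"B": -1}, gprs[2]),
    ]
    return MetabolicModel(metabolites=mets, reactions=reactions, objective="R3")


def _to_cobra(model: MetabolicModel):
    import cobra

    cm = cobra.Model("oracle")
    mets = {m["id"]: cobra.Metabolite(m["id"], compartment=m["compartment"])
            for m in model.metabolites}
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, lower_bound=rxn.lb, upper_bound=rxn.ub)
        cm.add_reactions([cr])
        cr.add_metabolites({mets[k]: v for k, v in rxn.stoichiometry.items()})
    cm.objective = model.objective
    return cm


class TestGPR:
    def test_parse_tree_structure(self):
        tree = parse_gpr("(gA and gB) or gC")
        assert tree.op == "or"
        assert tree.children[0].op == "and"
        assert {c.gene for c in tree.children[0].children} == {"gA", "gB"}
        assert tree.children[1].gene == "gC"

    @pytest.mark.parametrize("states, expected", [
        ({"gA": 1, "gB": 0, "gC": 1}, 1),
        ({"gA": 1, "gB": 0, "gC": 0}, 0),
        ({"gA": 1, "gB": 1, "gC": 0}, 1),
    ])
    def test_and_or_evaluation(self, states, expected):
        tree = parse_gpr("(gA and gB) or gC")
        assert eval_gpr(tree, states) == expected

    def test_empty_rule_and_missing_genes_default_active(self):
        assert eval_gpr(None, {}) == 1
        assert eval_gpr(parse_gpr("gX"), {}) == 1

    @pytest.mark.parametrize("bad", ["(gA and", "gA or or gB", "gA)", "and gB"])
    def test_malformed_rules_rejected(self, bad):
        with pytest.raises(GPRSyntaxError):
            parse_gpr(bad)

    def test_random_rules_match_truth_table_oracle(self):
        """Exhaustive truth-table comparison against python's own boolean
        evaluation of the same expression."""
        rng = np.random.default_rng(6)
        genes = ["g0", "g1", "g2", "g3"]
        for _ in range(25):
            terms = rng.choice(genes, size=4, replace=True)
            rule = (
                f"({terms[0]} and {terms[1]}) or ({terms[2]} and "
                f"({terms[3]} or {terms[0]}))"
            )
            tree = parse_gpr(rule)
            for bits in itertools.product([0, 1], repeat=4):
                states = dict(zip(genes, bits))
                expected = int(
                    eval(
                        rule.replace("and", " and ").replace("or", " or "),
                        {},
                        {g: bool(v) for g, v in states.items()},
                    )
                )
                assert eval_gpr(tree, states) == expected


class TestParseModel:
    def test_fixture_round_trip_parses_and_is_feasible(self, tmp_path, toy_model):
        path = tmp_path / "model.json"
        toy_model.to_json(path)
        model = parse_model(path)
        assert fba(model).objective_value == pytest.approx(
            fba(toy_model).objective_value
        )

    def test_inverted_bounds_rejected(self):
        payload = {
            "metabolites": [{"id": "A"}],
            "reactions": [
                {"id": "R", "lb": 1, "ub": 0, "metabolites": {"A": 1}},
            ],
            "objective": "R",
        }
        with pytest.raises(ModelValidationError, match="lb"):
            model_from_dict(payload)

    def test_unknown_metabolite_rejected(self):
        payload = {
            "metabolites": [{"id": "A"}],
            "reactions": [
                {"id": "R", "lb": 0, "ub": 1, "metabolites": {"ZZ": 1}},
            ],
            "objective": "R",
        }
        with pytest.raises(ModelValidationError, match="unknown metabolite"):
            model_from_dict(payload)

    def test_missing_objective_rejected(self):
        payload = {
            "metabolites": [{"id": "A"}],
            "reactions": [{"id": "R", "lb": 0, "ub": 1, "metabolites": {"A": 1}}],
            "objective": "NOPE",
        }
        with pytest.raises(ModelValidationError, match="objective"):
            model_from_dict(payload)


class TestFBA:
    def test_bottleneck_chain(self):
        assert fba(_chain_model()).objective_value == pytest.approx(5.0)

    def test_all_inactive_gives_zero(self):
        model = _chain_model()
        res = fba(model, {r.id: 0 for r in model.reactions})
        assert res.ok
        assert res.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_fixture_optimum_matches_cobra_oracle(self, toy_model):
        mine = fba(toy_model).objective_value
        oracle = _to_cobra(toy_model).optimize().objective_value
        assert mine == pytest.approx(oracle, abs=1e-6)


class TestMadeIntegrate:
    def test_all_transitions_zero_matches_everything(self, toy_model):
        genes = toy_model.genes
        de = pd.DataFrame({"d": 0, "w": 1.0}, index=genes)
        sol = made_integrate(toy_model, de, f=0.3)
        assert sol.objective_value == pytest.approx(sol.total_weight)
        assert sol.match_fraction == pytest.approx(1.0)
        assert (sol.gene_states["WT"] == sol.gene_states["KO"]).all()

    def test_gating_gene_down_on_sole_objective_path_cannot_match(self):
        model = _chain_model(gprs=("", "gMid", ""))
        de = pd.DataFrame({"d": [-1], "w": [5.0]}, index=["gMid"])
        sol = made_integrate(model, de, f=0.5)
        # turning gMid off would kill the KO objective entirely
        assert sol.objective_value == pytest.approx(0.0, abs=1e-9)
        assert not sol.matched["gMid"]
        assert sol.gene_states.at["gMid", "KO"] == 1

    def test_reaction_states_equal_gpr_of_gene_states(self, small_panel):
        from fibroprog.diffexpr import run_differential_expression
        from fibroprog.simulate import toy_metabolic_model as build

        studies, truth = small_panel
        model = build(truth)
        table = run_differential_expression(studies[0])
        de = de_input_from_stats(table)
        sol = made_integrate(model, de, f=0.3)
        for cond in ("WT", "KO"):
            states = dict(sol.gene_states[cond])
            for rxn in model.reactions:
                assert sol.reaction_states.at[rxn.id, cond] == eval_gpr(
                    rxn.gpr_tree, states
                )

    def test_infeasible_functionality_fraction_raises(self):
        model = _chain_model(gprs=("", "gMid", ""))
        de = pd.DataFrame({"d": [0], "w": [1.0]}, index=["gMid"])
        with pytest.raises(RuntimeError, match="f too high|status"):
            made_integrate(model, de, f=1.5)


class TestFVA:
    def test_inactive_reaction_reported_zero_without_solving(self):
        model = _chain_model()
        vstar = fba(model).objective_value
        res = fva(model, {"R2": 0, "R1": 1, "R3": 1}, f=0.0, reference_optimum=vstar)
        assert res.intervals.loc["R2"].tolist() == [0.0, 0.0]

    def test_forced_flux_at_full_functionality(self):
        model = _chain_model()
        vstar = fba(model).objective_value
        res = fva(model, None, f=1.0, reference_optimum=vstar)
        for rid in ("R1", "R2", "R3"):
            assert res.intervals.at[rid, "lo"] == pytest.approx(vstar, abs=1e-6)
            assert res.intervals.at[rid, "hi"] == pytest.approx(vstar, abs=1e-6)

    def test_fixture_intervals_match_cobra_oracle(self, toy_model):
        from cobra.flux_analysis import flux_variability_analysis

        vstar = fba(toy_model).objective_value
        mine = fva(toy_model, None, f=0.5, reference_optimum=vstar).intervals
        oracle = flux_variability_analysis(
            _to_cobra(toy_model), fraction_of_optimum=0.5
        )
        np.testing.assert_allclose(
            mine["lo"], oracle.loc[mine.index, "minimum"], atol=1e-5
        )
        np.testing.assert_allclose(
            mine["hi"], oracle.loc[mine.index, "maximum"], atol=1e-5
        )

    def test_lower_functionality_intervals_contain_higher(self, toy_model):
        vstar = fba(toy_model).objective_value
        loose = fva(toy_model, None, f=0.9, reference_optimum=vstar).intervals
        tight = fva(toy_model, None, f=1.0, reference_optimum=vstar).intervals
        assert (loose["lo"] <= tight["lo"] + 1e-6).all()
        assert (loose["hi"] >= tight["hi"] - 1e-6).all()


class TestClassifyReactions:
    def _mk(self, intervals: dict[str, tuple[float, float]]) -> FvaResult:
        table = pd.DataFrame(intervals, index=["lo", "hi"]).T
        return FvaResult(intervals=table)

    def test_capacity_rule_and_eps_branch(self):
        wt = self._mk({"r1": (0, 5), "r2": (0, 5), "r3": (0, 5)})
        ko = self._mk({"r1": (0, 8), "r2": (0, 2), "r3": (0, 5 + 1e-9)})
        states = pd.DataFrame({"WT": [1, 1, 1], "KO": [1, 1, 1]},
                              index=["r1", "r2", "r3"])
        labels = classify_reactions(wt, ko, states, eps=1e-6)
        assert labels.tolist() == ["up", "down", "unchanged"]

    def test_state_switch_overrides_capacity(self):
        wt = self._mk({"r1": (0, 1)})
        ko = self._mk({"r1": (0, 0)})
        states = pd.DataFrame({"WT": [1], "KO": [0]}, index=["r1"])
        assert classify_reactions(wt, ko, states).tolist() == ["down"]
        states_on = pd.DataFrame({"WT": [0], "KO": [1]}, index=["r1"])
        assert classify_reactions(ko, wt, states_on).tolist() == ["up"]

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(14)
        n = 30
        ids = [f"r{i}" for i in range(n)]
        wt = self._mk({r: tuple(sorted(rng.uniform(0, 10, 2))) for r in ids})
        ko = self._mk({r: tuple(sorted(rng.uniform(0, 10, 2))) for r in ids})
        states = pd.DataFrame(
            {"WT": rng.integers(0, 2, n), "KO": rng.integers(0, 2, n)}, index=ids
        )
        fwd = classify_reactions(wt, ko, states)
        swapped_states = states.rename(columns={"WT": "KO", "KO": "WT"})
        rev = classify_reactions(ko, wt, swapped_states)
        flip = {"up": "down", "down": "up", "unchanged": "unchanged"}
        assert rev.tolist() == [flip[c] for c in fwd.tolist()]


class TestSubsystemEnrichment:
    def _classes(self, model, down_ids):
        return pd.Series(
            ["down" if r.id in down_ids else "unchanged" for r in model.reactions],
            index=model.reaction_ids,
        )

    def test_exact_tail_example(self):
        # N=20, K=5, n=6, k=4 -> p = 540/38760
        from scipy.stats import hypergeom

        assert hypergeom.sf(3, 20, 5, 6) == pytest.approx(540 / 38760, abs=1e-12)

    def test_zero_overlap_has_p_one(self, toy_model):
        classes = self._classes(toy_model, {"HEX"})
        table = subsystem_enrichment(classes, toy_model)
        row = table[(table.subsystem == "Biomass") & (table.direction == "down")]
        assert row["p"].iloc[0] == pytest.approx(1.0)

    def test_no_changes_in_direction_gives_all_p_one(self, toy_model):
        classes = self._classes(toy_model, set())
        table = subsystem_enrichment(classes, toy_model)
        assert (table["p"] == 1.0).all()
        assert not table["significant"].any()

    def test_whole_model_subsystem_is_never_enriched(self):
        mets = [{"id": "A", "compartment": "c"}]
        reactions = [
            Reaction("R1", "", "Everything", 0, 5, {"A": 1}, ""),
            Reaction("R2", "", "Everything", 0, 5, {"A": -1}, ""),
        ]
        model = MetabolicModel(metabolites=mets, reactions=reactions, objective="R2")
        classes = pd.Series(["down", "down"], index=["R1", "R2"])
        table = subsystem_enrichment(classes, model)
        down = table[table.direction == "down"]
        assert np.allclose(down["p"], 1.0)

    def test_p_matches_direct_pmf_summation(self, toy_model):
        classes = self._classes(toy_model, {"FATP", "FACOAL", "CPT1", "BOX1", "HEX"})
        table = subsystem_enrichment(classes, toy_model)
        for _, row in table.iterrows():
            n_, k_, K_, N_ = int(row.n), int(row.k), int(row.K), int(row.N)
            tail = sum(
                math.comb(K_, i) * math.comb(N_ - K_, n_ - i)
                for i in range(k_, min(K_, n_) + 1)
            ) / math.comb(N_, n_) if n_ > 0 else 1.0
            assert row.p == pytest.approx(tail, abs=1e-12)
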