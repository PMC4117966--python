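import math

import numpy as np
import pytest

from hporank.annotations import AnnotationIndex
from hporank.fixtures import make_toy_fixture
from hporank.similarity import SimilarityKernel
from hporank.simulate import (
    SCENARIOS,
    DiseaseModel,
    DiseasePhenotype,
    add_imprecision,
    add_noise,
    build_cohort,
    load_cohort,
    load_disease_table,
    noise_count,
    noise_universe,
    sample_optimal,
    write_cohort,
    write_disease_table,
)

import io


@pytest.fixture(scope="module")
def toy():
    ont, idx, models = make_toy_fixture(n_terms=40, n_genes=12, seed=31)
    return ont, idx, models


def make_model(idx, gene, penetrances, genders=None):
    terms = sorted(idx.direct[gene])
    genders = genders or ["none"] * len(penetrances)
    return DiseaseModel(
        omim_id="OMIM:1",
        causative_gene=gene,
        phenotypes=tuple(
            DiseasePhenotype(term=t, penetrance=f, gender_restriction=g)
            for t, f, g in zip(terms, penetrances, genders)
        ),
    )


class TestSampleOptimal:
    def test_full_penetrance_includes_every_phenotype(self, toy):
        ont, idx, _ = toy
        gene = idx.genes[0]
        n = len(idx.direct[gene])
        model = make_model(idx, gene, [1.0] * n)
        for seed in range(5):
            p = sample_optimal(model, ont, idx, seed)
            assert p.optimal_terms == idx.direct[gene]

    def test_penetrance_controls_inclusion_frequency(self, toy):
        """Two phenotypes with penetrance 0.25 and 0.5: conditional on a
        non-empty patient, P(term present) = f / (1 - (1-f1)(1-f2));
        empirical frequencies within 3 standard errors."""
        ont, idx, _ = toy
        gene = idx.genes[0]
        model = make_model(idx, gene, [0.25, 0.5])
        t1, t2 = (ph.term for ph in model.phenotypes)
        rng = np.random.default_rng(123)
        n = 10_000
        hits1 = hits2 = 0
        for _ in range(n):
            p = sample_optimal(model, ont, idx, rng)
            hits1 += t1 in p.optimal_terms
            hits2 += t2 in p.optimal_terms
        p_nonempty = 1 - 0.75 * 0.5
        for hits, f in ((hits1, 0.25), (hits2, 0.5)):
            expected = f / p_nonempty
            se = math.sqrt(expected * (1 - expected) / n)
            assert abs(hits / n - expected) <= 3 * se

    def test_single_low_penetrance_term_always_present(self, toy):
        """The >=1-term constraint makes a single-phenotype draw degenerate."""
        ont, idx, _ = toy
        gene = idx.genes[0]
        model = make_model(idx, gene, [0.3])
        only = model.phenotypes[0].term
        rng = np.random.default_rng(9)
        for _ in range(500):
            p = sample_optimal(model, ont, idx, rng)
            assert p.optimal_terms == {only}

    def test_sex_sampled_roughly_uniform(self, toy):
        ont, idx, _ = toy
        model = make_model(idx, idx.genes[0], [1.0, 1.0])
        rng = np.random.default_rng(5)
        males = sum(
            sample_optimal(model, ont, idx, rng).sex == "male" for _ in range(2000)
        )
        assert 0.45 < males / 2000 < 0.55

    def test_sex_restricted_phenotype_never_conflicts(self, toy):
        ont, idx, _ = toy
        gene = idx.genes[1]
        terms = sorted(idx.direct[gene])[:2]
        model = DiseaseModel(
            omim_id="OMIM:2",
            causative_gene=gene,
            phenotypes=(
                DiseasePhenotype(term=terms[0], penetrance=1.0),
                DiseasePhenotype(
                    term=terms[1], penetrance=1.0, gender_restriction="female"
                ),
            ),
        )
        rng = np.random.default_rng(17)
        for _ in range(200):
            p = sample_optimal(model, ont, idx, rng)
            if p.sex == "male":
                assert terms[1] not in p.optimal_terms
            else:
                assert terms[1] in p.optimal_terms


class TestNoise:
    @pytest.mark.parametrize("n_optimal,expected", [(10, 5), (4, 2), (1, 0), (7, 3)])
    def test_noise_count_is_half_floored(self, n_optimal, expected):
        assert noise_count(n_optimal) == expected

    def test_noise_terms_unrelated_to_causative_gene(self, toy):
        ont, idx, _ = toy
        gene = idx.genes[0]
        model = make_model(idx, gene, [1.0] * len(idx.direct[gene]))
        rng = np.random.default_rng(3)
        forbidden = set(idx.direct[gene])
        for t in idx.direct[gene]:
            forbidden |= ont.ancestors(t)
        for _ in range(20):
            p = add_noise(sample_optimal(model, ont, idx, rng), idx, rng)
            assert p.scenario == "noise"
            assert p.terms == p.optimal_terms | p.noise_terms
            assert not (p.noise_terms & forbidden)
            # equivalently: no noise term annotates the gene, directly
            # or through a descendant
            for q in p.noise_terms:
                assert gene not in idx.propagated.get(q, frozenset())

    def test_noise_pool_exhaustion_is_an_error(self, toy):
        ont, idx, _ = toy
        gene = idx.genes[0]
        model = make_model(idx, gene, [1.0] * len(idx.direct[gene]))
        p = sample_optimal(model, ont, idx, 1)
        with pytest.raises(ValueError, match="noise"):
            add_noise(p, idx, 1, allowed=[])


class TestImprecision:
    def test_single_eligible_ancestor_always_chosen(self, toy_ontology, toy_index):
        from conftest import A, B

        p = _patient(toy_index, {B})
        out = add_imprecision(p, toy_ontology, 0)
        # B's proper ancestors are {A, root}; the root is barred
        assert out.terms == {A}

    def test_depth_one_term_kept_unchanged(self, toy_ontology, toy_index):
        from conftest import A

        p = _patient(toy_index, {A})  # only proper ancestor is the root
        out = add_imprecision(p, toy_ontology, 0)
        assert out.terms == {A}

    def test_replacements_are_proper_non_root_ancestors(self, toy):
        ont, idx, _ = toy
        gene = idx.genes[2]
        model = make_model(idx, gene, [1.0] * len(idx.direct[gene]))
        rng = np.random.default_rng(4)
        for _ in range(20):
            base = sample_optimal(model, ont, idx, rng)
            out = add_imprecision(base, ont, rng)
            assert 1 <= len(out.terms) <= len(base.optimal_terms)
            for t in out.terms:
                assert t != ont.root
                ok = any(
                    t == o or t in ont.ancestors(o) for o in base.optimal_terms
                )
                assert ok

    def test_per_term_score_contribution_never_increases(self, toy):
        """Each replacement's best match against the causative gene is
        bounded by the original term's: the anti-monotone mechanism that
        degrades ranks under imprecision."""
        ont, idx, _ = toy
        kernel = SimilarityKernel(idx)
        gene = idx.genes[2]
        best = kernel.best_match(gene)
        for t in idx.direct[gene]:
            ti = kernel.term_index[t]
            for a in ont.ancestors(t):
                if a == ont.root:
                    continue
                assert best[kernel.term_index[a]] <= best[ti] + 1e-12


class TestCohort:
    def test_size_is_diseases_times_patients_times_scenarios(self, toy):
        ont, idx, models = toy
        cohort = build_cohort(models, ont, idx, 4, seed=0)
        assert len(cohort) == len(models) * 4 * len(SCENARIOS)

    def test_single_scenario_cohort(self, toy):
        ont, idx, models = toy
        cohort = build_cohort(models, ont, idx, 1, scenarios=("optimal",), seed=0)
        assert len(cohort) == len(models)
        assert all(p.scenario == "optimal" for p in cohort)

    def test_same_seed_reproduces_cohort_exactly(self, toy):
        ont, idx, models = toy
        a = build_cohort(models, ont, idx, 3, seed=11)
        b = build_cohort(models, ont, idx, 3, seed=11)
        assert a == b

    def test_noise_terms_shared_between_noise_and_combined_rows(self, toy):
        ont, idx, models = toy
        cohort = build_cohort(models, ont, idx, 3, seed=2)
        by_key = {(p.patient_id, p.scenario): p for p in cohort}
        for (pid, scen), p in by_key.items():
            if scen == "imprecision_noise":
                noisy = by_key[(pid, "noise")]
                imp = by_key[(pid, "imprecision")]
                assert p.noise_terms == noisy.noise_terms
                assert p.terms == imp.terms | noisy.noise_terms
                assert p.optimal_terms == noisy.optimal_terms == imp.optimal_terms

    def test_every_patient_has_at_least_one_term(self, toy):
        ont, idx, models = toy
        cohort = build_cohort(models, ont, idx, 5, seed=3)
        assert all(len(p.terms) >= 1 for p in cohort)

    def test_expected_optimal_count_matches_penetrance_sum(self, toy):
        """With one fully penetrant phenotype the >=1 constraint never
        binds, so E[#terms] = sum of penetrances; check within 3 SEs."""
        ont, idx, _ = toy
        gene = idx.genes[0]
        fs = [1.0] + [0.4] * (len(idx.direct[gene]) - 1)
        model = make_model(idx, gene, fs)
        rng = np.random.default_rng(8)
        n = 10_000
        counts = [
            len(sample_optimal(model, ont, idx, rng).optimal_terms) for _ in range(n)
        ]
        expected = sum(fs)
        var = sum(f * (1 - f) for f in fs)
        se = math.sqrt(var / n)
        assert abs(np.mean(counts) - expected) <= 3 * se


class TestTableIO:
    def test_disease_table_round_trip(self, toy):
        _, _, models = toy
        buf = io.StringIO()
        write_disease_table(models, buf)
        buf.seek(0)
        again = load_disease_table(buf)
        assert [m.omim_id for m in again] == [m.omim_id for m in sorted(models, key=lambda m: m.omim_id)]
        for a, b in zip(again, sorted(models, key=lambda m: m.omim_id)):
            assert a.causative_gene == b.causative_gene
            assert [p.term for p in a.phenotypes] == [p.term for p in b.phenotypes]
            for pa, pb in zip(a.phenotypes, b.phenotypes):
                assert pa.penetrance == pytest.approx(pb.penetrance, abs=1e-4)

    def test_cohort_round_trip(self, toy):
        ont, idx, models = toy
        cohort = build_cohort(models, ont, idx, 2, seed=5)
        buf = io.StringIO()
        write_cohort(cohort, buf)
        buf.seek(0)
        again = load_cohort(buf)
        assert again == cohort

    def test_invalid_penetrance_rejected(self):
        with pytest.raises(ValueError):
            DiseasePhenotype(term="T:1", penetrance=0.0)
        with pytest.raises(ValueError):
            DiseasePhenotype(term="T:1", penetrance=1.2)


def _patient(idx, terms):
    from hporank.simulate import SimulatedPatient

    return SimulatedPatient(
        patient_id="p1",
        disease="OMIM:1",
        causative_gene=idx.genes[0],
        sex="female",
        optimal_terms=frozenset(terms),
    )
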