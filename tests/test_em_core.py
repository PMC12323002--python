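import math
import random

import numpy as np
import pytest

from taxfun.em_core import (
    UNANNOTATED,
    BiomassEstimate,
    CompatibilityMap,
    aggregate_biomass,
    aggregate_to_level,
    build_compatibility,
    estimate_biomass,
    estimate_function_abundance,
)
from taxfun.io_model import FunctionAnnotation, PeptideEvidence, ProteinRecord
from taxfun.synthetic_data import CommunitySpec, default_lineages, generate_community, generate_sample
from taxfun.taxonomy import CANONICAL_RANKS

from helpers import grid_argmax_1d, grid_argmax_nd, stage1_loglik

MF = "molecular_function"


def _pep(seq, area, count=1):
    return PeptideEvidence(seq, 1e-6, area, count)


def _compat(taxon_sets, mf_pairs=None):
    taxon_sets = {p: frozenset(s) for p, s in taxon_sets.items()}
    pair_sets = {}
    if mf_pairs:
        pair_sets = {(p, MF): frozenset(pairs) for p, pairs in mf_pairs.items()}
    return CompatibilityMap(taxon_sets=taxon_sets, pair_sets=pair_sets)


class TestBuildCompatibility:
    def test_single_annotated_protein(self):
        peptides = [_pep("PEP1", 10.0)]
        proteins = [ProteinRecord("ACC1", "A", 1e-5, frozenset({"PEP1"}))]
        anns = [FunctionAnnotation("ACC1", frozenset({("GO:0000001", MF), ("GO:0000002", MF)}))]
        compat = build_compatibility(peptides, proteins, anns, {"A"})
        assert compat.taxon_sets == {"PEP1": frozenset({"A"})}
        assert compat.pair_sets[("PEP1", MF)] == frozenset({("A", "GO:0000001"), ("A", "GO:0000002")})

    def test_unannotated_taxon_gets_sink_pair(self):
        peptides = [_pep("PEP1", 10.0)]
        proteins = [
            ProteinRecord("ACC1", "A", 1e-5, frozenset({"PEP1"})),
            ProteinRecord("ACC2", "B", 1e-5, frozenset({"PEP1"})),
        ]
        anns = [FunctionAnnotation("ACC1", frozenset({("GO:0000001", MF)}))]
        compat = build_compatibility(peptides, proteins, anns, {"A", "B"})
        assert compat.pair_sets[("PEP1", MF)] == frozenset(
            {("A", "GO:0000001"), ("B", UNANNOTATED)}
        )

    def test_orphan_peptide_dropped_with_warning(self):
        peptides = [_pep("PEPX", 10.0)]
        with pytest.warns(UserWarning, match="dropped 1 peptide"):
            compat = build_compatibility(peptides, [], [], {"A"})
        assert compat.taxon_sets == {}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_direct_set_construction_oracle(self, seed):
        rng = random.Random(seed)
        taxa = [f"t{i}" for i in range(4)]
        peptide_pool = [f"PEP{i}" for i in range(12)]
        go_pool = [f"GO:{i:07d}" for i in range(1, 8)]
        proteins = [
            ProteinRecord(
                f"ACC{i}", rng.choice(taxa), 1e-5, frozenset(rng.sample(peptide_pool, rng.randrange(1, 5)))
            )
            for i in range(8)
        ]
        anns = [
            FunctionAnnotation(p.accession, frozenset((g, MF) for g in rng.sample(go_pool, rng.randrange(0, 3))))
            for p in proteins
        ]
        peptides = [_pep(p, 1.0) for p in peptide_pool]
        identified = set(taxa[:3])
        compat = build_compatibility(peptides, proteins, anns, identified)
        ann_of = {a.accession: a.terms for a in anns}
        for pep in peptide_pool:
            carriers = [p for p in proteins if pep in p.peptides and p.taxon in identified]
            expected_taxa = {p.taxon for p in carriers}
            if not expected_taxa:
                assert pep not in compat.taxon_sets
                continue
            assert compat.taxon_sets[pep] == expected_taxa
            expected_pairs = set()
            for t in expected_taxa:
                terms = {
                    g for p in carriers if p.taxon == t for g, a in ann_of[p.accession] if a == MF
                }
                if terms:
                    expected_pairs.update((t, g) for g in terms)
                else:
                    expected_pairs.add((t, UNANNOTATED))
            assert compat.pair_sets[(pep, MF)] == expected_pairs


class TestEstimateBiomass:
    def test_single_taxon_normalizes_immediately(self):
        compat = _compat({"PEP1": {"A"}})
        result = estimate_biomass([_pep("PEP1", 5.0)], compat)
        assert result.probabilities == {"A": 1.0}
        assert result.converged

    def test_fully_shared_equal_areas_is_symmetric(self):
        compat = _compat({"PEP1": {"A", "B"}, "PEP2": {"A", "B"}})
        result = estimate_biomass([_pep("PEP1", 3.0), _pep("PEP2", 3.0)], compat)
        assert result.probabilities["A"] == pytest.approx(0.5, abs=1e-12)
        assert result.probabilities["B"] == pytest.approx(0.5, abs=1e-12)

    def test_matches_grid_search_likelihood_oracle(self):
        # unique evidence 99 vs 1 plus one fully shared peptide of area 1
        compat = _compat({"U_A": {"A"}, "U_B": {"B"}, "SH": {"A", "B"}})
        peptides = [_pep("U_A", 99.0), _pep("U_B", 1.0), _pep("SH", 1.0)]
        result = estimate_biomass(peptides, compat)
        groups = {frozenset({"A"}): 99.0, frozenset({"B"}): 1.0, frozenset({"A", "B"}): 1.0}
        w_star = grid_argmax_1d(lambda w: stage1_loglik(groups, {"A": w, "B": 1.0 - w}))
        assert result.probabilities["A"] == pytest.approx(w_star, abs=1e-4)

    def test_zero_noise_ratio_mixture_recovered_exactly(self):
        # four species at 1:2:2:4, unique peptides only, no noise
        spec = CommunitySpec(
            species=default_lineages(4),
            biomass_ratios=(1, 2, 2, 4),
            proteins_per_species=5,
            peptides_per_protein=(10, 10),
            noise_sigma=0.0,
            seed=42,
        )
        community = generate_community(spec)
        sample = generate_sample(community)
        compat = build_compatibility(
            sample, community.proteins, list(community.annotations), set(spec.biomass_truth)
        )
        result = estimate_biomass(sample, compat)
        for taxon, expected in spec.biomass_truth.items():
            assert result.probabilities[taxon] == pytest.approx(expected, abs=1e-12)

    def test_log_likelihood_monotone_across_iterations(self):
        compat = _compat({"P1": {"A", "B"}, "P2": {"B", "C"}, "P3": {"A"}, "P4": {"C"}})
        peptides = [_pep("P1", 5.0), _pep("P2", 2.0), _pep("P3", 7.0), _pep("P4", 1.0)]
        groups = {
            frozenset({"A", "B"}): 5.0,
            frozenset({"B", "C"}): 2.0,
            frozenset({"A"}): 7.0,
            frozenset({"C"}): 1.0,
        }
        previous = -math.inf
        import warnings as _warnings

        for n_iter in range(1, 30):
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # truncated runs warn by design
                result = estimate_biomass(peptides, compat, tol=0.0, max_iter=n_iter)
            ll = stage1_loglik(groups, result.probabilities)
            assert ll >= previous - 1e-12
            previous = ll

    def test_all_zero_areas_raises_with_fallback_advice(self):
        compat = _compat({"P1": {"A"}})
        with pytest.raises(ValueError, match="spectral_count"):
            estimate_biomass([_pep("P1", 0.0)], compat)
        result = estimate_biomass([_pep("P1", 0.0)], compat, use_spectral_counts_only=True)
        assert result.probabilities == {"A": 1.0}

    def test_non_convergence_flag(self):
        compat = _compat({"P1": {"A", "B"}, "P2": {"A"}, "P3": {"B"}})
        peptides = [_pep("P1", 1.0), _pep("P2", 3.0), _pep("P3", 2.0)]
        with pytest.warns(UserWarning, match="did not converge"):
            result = estimate_biomass(peptides, compat, tol=1e-30, max_iter=2)
        assert not result.converged
        assert sum(result.probabilities.values()) == pytest.approx(1.0, abs=1e-9)

    def test_permutation_invariance_bit_identical(self):
        rng = random.Random(7)
        taxa = ["A", "B", "C"]
        taxon_sets = {
            f"P{i}": set(rng.sample(taxa, rng.randrange(1, 4))) for i in range(25)
        }
        peptides = [_pep(p, rng.uniform(0.5, 10.0), rng.randrange(1, 4)) for p in taxon_sets]
        compat = _compat(taxon_sets)
        baseline = estimate_biomass(peptides, compat)
        shuffled = list(peptides)
        rng.shuffle(shuffled)
        result = estimate_biomass(shuffled, compat)
        assert result.probabilities == baseline.probabilities  # exact, not approx


class TestEstimateFunctionAbundance:
    def test_single_taxon_single_term(self):
        compat = _compat({"P1": {"A"}}, {"P1": {("A", "GO:0000001")}})
        biomass = BiomassEstimate({"A": 1.0}, 1, True)
        table = estimate_function_abundance([_pep("P1", 2.0)], compat, biomass, MF)
        assert table.joint == {("A", "GO:0000001"): 1.0}

    def test_disjoint_term_support_reduces_to_proportions(self):
        compat = _compat(
            {"P1": {"A"}, "P2": {"A"}},
            {"P1": {("A", "k1")}, "P2": {("A", "k2")}},
        )
        # areas 3 and 1 with no sharing: direct 0.75 / 0.25 split
        biomass = BiomassEstimate({"A": 1.0}, 1, True)
        table = estimate_function_abundance([_pep("P1", 3.0), _pep("P2", 1.0)], compat, biomass, MF)
        assert table.joint[("A", "k1")] == pytest.approx(0.75, abs=1e-9)
        assert table.joint[("A", "k2")] == pytest.approx(0.25, abs=1e-9)

    def test_matches_two_parameter_grid_oracle(self):
        p = {"A": 0.6, "B": 0.4}
        mf_pairs = {
            "P1": {("A", "k1")},
            "P2": {("A", "k2"), ("B", "k1")},
            "P3": {("A", "k1"), ("B", "k2")},
            "P4": {("B", "k2")},
        }
        weights = {"P1": 3.0, "P2": 2.0, "P3": 2.0, "P4": 1.0}
        compat = _compat({pep: {t for t, _ in pairs} for pep, pairs in mf_pairs.items()}, mf_pairs)
        peptides = [_pep(pep, w) for pep, w in weights.items()]
        biomass = BiomassEstimate(p, 1, True)
        table = estimate_function_abundance(peptides, compat, biomass, MF)

        def loglik(params):
            a, b = params  # phi(k1|A), phi(k1|B)
            phi = {("A", "k1"): a, ("A", "k2"): 1 - a, ("B", "k1"): b, ("B", "k2"): 1 - b}
            total = 0.0
            for pep, pairs in mf_pairs.items():
                mix = sum(p[t] * phi[(t, k)] for t, k in pairs)
                if mix <= 0:
                    return -np.inf
                total += weights[pep] * np.log(mix)
            return total

        a_star, b_star = grid_argmax_nd(loglik, 2)
        assert table.joint[("A", "k1")] / p["A"] == pytest.approx(a_star, abs=1e-4)
        assert table.joint[("B", "k1")] / p["B"] == pytest.approx(b_star, abs=1e-4)

    def test_biomass_constraint_holds_per_taxon(self):
        rng = random.Random(3)
        taxa = ["A", "B", "C"]
        terms = ["k1", "k2", "k3"]
        mf_pairs = {}
        taxon_sets = {}
        for i in range(20):
            pairs = {
                (rng.choice(taxa), rng.choice(terms)) for _ in range(rng.randrange(1, 4))
            }
            mf_pairs[f"P{i}"] = pairs
            taxon_sets[f"P{i}"] = {t for t, _ in pairs}
        compat = _compat(taxon_sets, mf_pairs)
        peptides = [_pep(pep, rng.uniform(0.1, 5.0)) for pep in mf_pairs]
        biomass = estimate_biomass(peptides, compat)
        table = estimate_function_abundance(peptides, compat, biomass, MF)
        totals = table.per_taxon_totals()
        for taxon, p_t in biomass.probabilities.items():
            assert totals[taxon] == pytest.approx(p_t, abs=1e-9)

    def test_taxon_without_aspect_evidence_goes_to_sink(self):
        compat = _compat({"P1": {"A"}}, {"P1": {("A", "k1")}})
        biomass = BiomassEstimate({"A": 0.7, "B": 0.3}, 1, True)
        table = estimate_function_abundance([_pep("P1", 1.0)], compat, biomass, MF)
        assert table.joint[("B", UNANNOTATED)] == pytest.approx(0.3, abs=1e-12)


class TestAggregation:
    def test_single_species_identical_at_all_levels(self, full_lineage_tree):
        from taxfun.em_core import FunctionAbundanceTable

        joint = {("s1", "k1"): 0.6, ("s1", "k2"): 0.4}
        table = FunctionAbundanceTable(aspect=MF, joint=joint)
        counts = set()
        for level in CANONICAL_RANKS:
            agg = aggregate_to_level(table, full_lineage_tree, level)
            counts.add(len(agg.joint))
            assert sorted(agg.joint.values()) == sorted(joint.values())
        assert counts == {2}

    def test_two_species_one_genus_sums(self, full_lineage_tree):
        from taxfun.em_core import FunctionAbundanceTable

        table = FunctionAbundanceTable(aspect=MF, joint={("s1", "k"): 0.3, ("s2", "k"): 0.2})
        agg = aggregate_to_level(table, full_lineage_tree, "genus")
        assert agg.joint == {("g1", "k"): pytest.approx(0.5)}

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_groupby_oracle(self, full_lineage_tree, seed):
        from taxfun.em_core import FunctionAbundanceTable

        rng = random.Random(seed)
        species = ["s1", "s2", "s3", "s4"]
        terms = [f"k{i}" for i in range(5)]
        joint = {
            (s, k): rng.uniform(0, 1) for s in species for k in terms if rng.random() < 0.7
        }
        table = FunctionAbundanceTable(aspect=MF, joint=joint)
        # ancestors of the fixture, known statically
        ancestor = {
            "genus": {"s1": "g1", "s2": "g1", "s3": "g2", "s4": "g2"},
            "family": {s: "f1" for s in species},
            "root": {s: "root" for s in species},
        }
        for level, mapping in ancestor.items():
            agg = aggregate_to_level(table, full_lineage_tree, level)
            expected: dict = {}
            for (s, k), v in joint.items():
                key = (mapping[s], k)
                expected[key] = expected.get(key, 0.0) + v
            assert set(agg.joint) == set(expected)
            for key in expected:
                assert agg.joint[key] == pytest.approx(expected[key], abs=1e-12)

    def test_unique_term_set_constant_across_levels(self, full_lineage_tree):
        from taxfun.em_core import FunctionAbundanceTable

        table = FunctionAbundanceTable(
            aspect=MF, joint={("s1", "k1"): 0.2, ("s3", "k1"): 0.3, ("s4", "k2"): 0.5}
        )
        reference = table.unique_terms()
        for level in CANONICAL_RANKS:
            assert aggregate_to_level(table, full_lineage_tree, level).unique_terms() == reference

    def test_biomass_aggregation_conserves_mass(self, full_lineage_tree):
        probabilities = {"s1": 0.1, "s2": 0.2, "s3": 0.3, "s4": 0.4}
        for level in CANONICAL_RANKS:
            agg = aggregate_biomass(probabilities, full_lineage_tree, level)
            assert sum(agg.values()) == pytest.approx(1.0, abs=1e-12)
        genus = aggregate_biomass(probabilities, full_lineage_tree, "genus")
        assert genus == {"g1": pytest.approx(0.3), "g2": pytest.approx(0.7)}
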