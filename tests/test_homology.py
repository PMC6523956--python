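"""Local alignment against a brute-force DP oracle, E-value statistics,
domain-profile scanning and three-strategy family mining."""

import math
import random

import pytest

from oracles import local_affine_score
from soxkit import homology
from soxkit.homology import (
    DomainProfile,
    align_local,
    assign_group,
    evalue_of,
    mine_family,
    scan_domain,
)
from soxkit.seqio import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestAlignLocal:
    def test_matches_bruteforce_dp_oracle_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(200):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(1, 25)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(1, 25)))
            assert align_local(a, b).raw_score == local_affine_score(a, b)

    def test_self_alignment_identity_and_score(self):
        seq = "MKVLAWGRET"
        res = align_local(seq, seq)
        assert res.identity == 1.0
        matrix = homology.make_aligner().substitution_matrix
        assert res.raw_score == sum(matrix[c, c] for c in seq)
        assert res.query_span == (1, len(seq))

    def test_all_negative_scores_give_empty_alignment(self):
        # W-vs-P scores -4 under BLOSUM62: no positive-scoring cell
        res = align_local("WWWW", "PPPP")
        assert res.raw_score == 0.0
        assert res.query_span is None

    def test_score_symmetric_under_symmetric_matrix(self):
        rng = random.Random(7)
        for _ in range(20):
            a = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
            b = "".join(rng.choice(AA) for _ in range(rng.randint(5, 30)))
            assert align_local(a, b).raw_score == align_local(b, a).raw_score

    def test_unknown_residue_scored_not_raised(self):
        res = align_local("MKVBJZ", "MKVBJZ")  # odd letters -> X column
        assert res.raw_score >= 0


class TestEvalue:
    def test_formula_against_hand_computation(self):
        # E = K*m*n*exp(-lambda*S) with the gapped BLOSUM62 constants
        expected = 0.041 * 400 * 100000 * math.exp(-0.267 * 100)
        assert evalue_of(100, 400, 100000) == pytest.approx(expected, rel=1e-6)

    def test_monotone_decreasing_in_score(self):
        evs = [evalue_of(s, 300, 10000) for s in range(0, 200, 10)]
        assert all(x > y for x, y in zip(evs, evs[1:]))

    def test_linear_in_database_size(self):
        assert evalue_of(50, 300, 2000) == pytest.approx(
            2 * evalue_of(50, 300, 1000)
        )

    def test_nonpositive_lengths_rejected(self):
        with pytest.raises(ValueError):
            evalue_of(50, 0, 1000)


class TestDomainScan:
    @pytest.fixture()
    def profile(self, default_sim):
        return DomainProfile.from_alignment(list(default_sim.references.values()))

    def test_consensus_planted_in_flanks_found_once(self, profile):
        rng = random.Random(3)
        flank = lambda n: "".join(rng.choice(AA) for _ in range(n))
        prot = ProteinRecord("p", "g", flank(50) + profile.consensus() + flank(60))
        hits = scan_domain(prot, profile)
        assert len(hits) == 1
        assert hits[0].start == 51 and hits[0].end == 51 + 78

    def test_random_background_has_no_hits(self, profile):
        rng = random.Random(11)
        for i in range(20):
            prot = ProteinRecord(
                f"bg{i}", f"bg{i}",
                "".join(rng.choice(AA) for _ in range(400)),
            )
            assert scan_domain(prot, profile) == []

    def test_protein_shorter_than_profile_gives_empty(self, profile):
        prot = ProteinRecord("s", "s", "A" * 78)
        assert scan_domain(prot, profile) == []

    def test_profile_tsv_round_trip(self, profile, tmp_path):
        path = tmp_path / "profile.tsv"
        profile.to_tsv(path)
        again = DomainProfile.from_tsv(path)
        # the TSV stores 6 decimals
        assert again.log_odds == pytest.approx(profile.log_odds, abs=1e-6)


class TestMineFamily:
    def test_recovers_exactly_the_planted_members(self, default_sim, mined_members):
        assert {m.gene_id for m in mined_members} == set(
            default_sim.truth.family_gene_ids
        )

    def test_groups_match_planted_truth(self, default_sim, mined_members):
        for m in mined_members:
            assert m.group == default_sim.truth.group_of[m.gene_id]

    def test_domain_ablated_control_excluded(self, default_sim, mined_members):
        ablated = set(default_sim.truth.ablated_gene_ids)
        assert ablated  # the default genome plants one negative control
        assert not ablated & {m.gene_id for m in mined_members}

    def test_invariant_to_record_order(self, default_sim, sim_profile, mined_members):
        shuffled = list(reversed(default_sim.proteins))
        again = mine_family(shuffled, default_sim.seeds, sim_profile,
                            references=default_sim.references)
        assert again == mined_members

    def test_zero_thresholds_give_empty_result(self, default_sim, sim_profile):
        members = mine_family(
            default_sim.proteins[:20], default_sim.seeds, sim_profile,
            evalue_seed=1e-300, evalue_domain=1e-300,
        )
        assert members == []

    def test_empty_seed_set_rejected(self, default_sim, sim_profile):
        with pytest.raises(ValueError, match="seed"):
            mine_family(default_sim.proteins[:5], [], sim_profile)


class TestAssignGroup:
    def test_identical_reference_wins_with_full_identity(self, default_sim):
        refs = default_sim.references
        group, ref, ident = assign_group(refs["E"], refs)
        assert (group, ident) == ("E", 1.0)

    def test_below_identity_threshold_unassigned(self):
        refs = {"E": "A" * 79}
        seq = "A" * 51 + "W" * 28  # ~65% identity to the reference
        group, _, ident = assign_group(seq, refs)
        assert group == "unassigned"
        assert ident < 0.70
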