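"""Probe-library design: SNV series, replicates, ablations, composites,
backgrounds and manifest assembly."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nextpbm.probe_design import (
    DesignManifest,
    SeedSite,
    assemble_design,
    expand_replicates,
    find_eice,
    has_intact_eice,
    make_ablation_probes,
    make_background_probes,
    make_snv_probes,
    make_synthetic_composite,
)
from nextpbm.sequences import contains_motif, revcomp

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


def brute_force_hamming1(seq):
    out = set()
    for pos, base in itertools.product(range(len(seq)), "ACGT"):
        if seq[pos] != base:
            out.add(seq[:pos] + base + seq[pos + 1 :])
    return out


class TestSNVProbes:
    @pytest.mark.parametrize(
        "sequence", ["ACGT", "AAAAAAAAAAAAAAAAAAAA", "ACTGGGAATCGAAACTGCAT"]
    )
    def test_equals_hamming1_enumeration(self, sequence):
        """The SNV series is exactly the Hamming-1 neighborhood: 3L distinct
        sequences, each covering all 4 bases per position together with the
        seed."""
        seed = SeedSite("s", sequence)
        variants = make_snv_probes(seed)
        assert len(variants) == 3 * len(sequence)
        assert set(variants) == brute_force_hamming1(sequence)
        assert len(set(variants)) == len(variants)
        for pos in range(len(sequence)):
            bases_at_pos = {v[pos] for v in variants} | {sequence[pos]}
            assert bases_at_pos == set("ACGT")

    def test_20bp_seed_yields_60_probes(self):
        seed = SeedSite("s", "ACTGGGAATCGAAACTGCAT")
        assert len(make_snv_probes(seed)) == 60

    def test_deterministic_order_position_major(self):
        variants = make_snv_probes(SeedSite("s", "AC"))
        assert variants == ["CC", "GC", "TC", "AA", "AG", "AT"]

    def test_rejects_non_acgt_with_position(self):
        with pytest.raises(ValueError, match="position 2"):
            SeedSite("s", "ACNT")
        with pytest.raises(ValueError):
            SeedSite("s", "")


class TestExpandReplicates:
    def test_ten_spots_per_unique_site(self):
        records = expand_replicates("ACTGGGAATCGAAACTGCAT", 5, seed_id="s")
        assert len(records) == 10
        assert sum(r.orientation == "fwd" for r in records) == 5
        assert {r.replicate_index for r in records} == {1, 2, 3, 4, 5}
        assert len({r.probe_id for r in records}) == 10

    def test_rev_records_carry_reverse_complement(self):
        records = expand_replicates("AACG", 2, seed_id="s")
        fwd = [r for r in records if r.orientation == "fwd"][0]
        rev = [r for r in records if r.orientation == "rev"][0]
        assert fwd.variable_region == "AACG"
        assert rev.variable_region == "CGTT"
        assert rev.unique_seq == "AACG"

    def test_full_sequence_embeds_scaffold(self):
        (r, *_) = expand_replicates("ACGT", 1, seed_id="s")
        assert r.full_sequence.startswith("ACGT")
        assert len(r.full_sequence) == 4 + 24

    def test_rejects_zero_replicates(self):
        with pytest.raises(ValueError):
            expand_replicates("ACGT", 0, seed_id="s")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(dna)
    def test_revcomp_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq


class TestAblation:
    def test_ets_ablation_removes_core_keeps_irf(self, eice_seed):
        abl_ets, abl_irf = make_ablation_probes(eice_seed, (4, 8), (10, 15))
        assert "GGAA" not in abl_ets.sequence
        assert "TTCC" not in abl_ets.sequence
        assert abl_ets.sequence[10:15] == "GAAAC"  # IRF half-site intact
        # IRF ablation keeps the ETS core
        assert abl_irf.sequence[4:8] == "GGAA"
        assert "GAAA" not in abl_irf.sequence[9:]
        assert "TTTC" not in abl_irf.sequence[9:]

    def test_unmutated_positions_identical(self, eice_seed):
        abl_ets, abl_irf = make_ablation_probes(eice_seed, (4, 8), (10, 15))
        for i in range(20):
            if not (4 <= i < 8):
                assert abl_ets.sequence[i] == eice_seed.sequence[i]
            if not (10 <= i < 15):
                assert abl_irf.sequence[i] == eice_seed.sequence[i]

    def test_replacement_differs_at_every_position(self, eice_seed):
        abl_ets, abl_irf = make_ablation_probes(eice_seed, (4, 8), (10, 15))
        assert all(
            a != b
            for a, b in zip(abl_ets.sequence[4:8], eice_seed.sequence[4:8])
        )
        assert all(
            a != b
            for a, b in zip(abl_irf.sequence[10:15], eice_seed.sequence[10:15])
        )

    def test_overlapping_spans_rejected(self, eice_seed):
        with pytest.raises(ValueError, match="overlap"):
            make_ablation_probes(eice_seed, (4, 8), (6, 11))

    def test_out_of_bounds_span_rejected(self, eice_seed):
        with pytest.raises(ValueError):
            make_ablation_probes(eice_seed, (4, 8), (16, 21))


class TestSyntheticComposite:
    def test_places_irf_half_site_with_two_base_linker(self):
        weak = SeedSite("w", "ACTGGGAATCTCTCTCTCAT", category_label="weak")
        comp = make_synthetic_composite(weak)
        assert comp.sequence[4:8] == "GGAA"
        assert comp.sequence[10:15] == "GAAAC"
        assert len(comp.sequence) == 20
        # linker and flanks come from the weak site
        assert comp.sequence[8:10] == weak.sequence[8:10]
        assert comp.sequence[:4] == weak.sequence[:4]
        assert comp.sequence[15:] == weak.sequence[15:]
        assert has_intact_eice(comp.sequence)

    def test_deterministic(self):
        weak = SeedSite("w", "ACTGGGAATCTCTCTCTCAT", category_label="weak")
        assert (
            make_synthetic_composite(weak).sequence
            == make_synthetic_composite(weak).sequence
        )

    def test_reverse_strand_core_handled(self):
        # GGAA only on the reverse strand (TTCC forward)
        weak = SeedSite("w", "ACTCTCTCTCTTCCTCTCAT", category_label="weak")
        comp = make_synthetic_composite(weak)
        assert has_intact_eice(comp.sequence)
        assert len(comp.sequence) == 20

    def test_core_too_close_to_edge_fails(self):
        weak = SeedSite("w", "ACTCTCTCTCTCTCTGGAAT", category_label="weak")
        with pytest.raises(ValueError, match="w"):
            make_synthetic_composite(weak)

    def test_no_core_fails(self):
        weak = SeedSite("w", "ACTCTCTCTCTCTCTCTCAT", category_label="weak")
        with pytest.raises(ValueError, match="no GGAA core"):
            make_synthetic_composite(weak)


class TestFindEice:
    def test_forward_and_reverse_detection(self, eice_seed):
        assert find_eice(eice_seed.sequence) == (4, "+")
        rc = revcomp(eice_seed.sequence)
        offset, strand = find_eice(rc)
        assert strand == "-"
        # the reported forward-strand window carries the architecture on
        # the reverse strand
        assert rc[offset : offset + 11] == revcomp(eice_seed.sequence[4:15])


class TestBackgroundProbes:
    def test_excludes_core_motifs_both_strands(self):
        probes = make_background_probes(500, 20, rng_seed=3)
        assert len(probes) == 500
        for p in probes:
            for motif in ("GGAA", "TTCC", "GAAA", "TTTC"):
                assert motif not in p.sequence
        assert len({p.sequence for p in probes}) == 500

    def test_reproducible_from_seed(self):
        a = make_background_probes(50, 20, rng_seed=7)
        b = make_background_probes(50, 20, rng_seed=7)
        assert [p.sequence for p in a] == [p.sequence for p in b]

    def test_uniform_base_composition(self):
        probes = make_background_probes(
            10000, 20, rng_seed=5, exclusion_motifs=()
        )
        joined = "".join(p.sequence for p in probes)
        counts = np.array([joined.count(b) for b in "ACGT"]) / len(joined)
        assert np.allclose(counts, 0.25, atol=0.01)

    def test_impossible_exclusion_fails(self):
        with pytest.raises(RuntimeError, match="rejection sampling"):
            make_background_probes(
                10, 4, rng_seed=0, max_attempts_per_probe=20,
                exclusion_motifs=tuple(
                    "".join(t) for t in itertools.product("ACGT", repeat=2)
                ),
            )


class TestAssembleDesign:
    def test_one_seed_with_snv_series_gives_610_spots(self, eice_seed):
        manifest = assemble_design([eice_seed], snv_seed_ids=["eice1"])
        assert len(manifest.unique_sequences) == 61
        assert manifest.n_spots == 610

    def test_empty_design_is_valid(self, tmp_path):
        manifest = assemble_design([])
        assert manifest.n_spots == 0
        out = tmp_path / "design.tsv"
        manifest.write_tsv(out)
        assert out.read_text().startswith("probe_id\t")

    def test_seed_only_scaling(self):
        seeds = [
            SeedSite(f"s{i}", p.sequence)
            for i, p in enumerate(
                make_background_probes(100, 20, rng_seed=2, exclusion_motifs=())
            )
        ]
        manifest = assemble_design(seeds)
        assert manifest.n_spots == 100 * 10

    def test_capacity_failure_reports_accounting(self, eice_seed):
        with pytest.raises(ValueError, match="capacity"):
            assemble_design([eice_seed], snv_seed_ids=["eice1"], max_spots=600)

    def test_duplicate_seed_ids_rejected(self, eice_seed):
        with pytest.raises(ValueError, match="unique"):
            assemble_design([eice_seed, eice_seed])

    def test_tsv_round_trip(self, tmp_path, eice_seed):
        manifest = assemble_design(
            [eice_seed], snv_seed_ids=["eice1"], ablation_seed_ids=["eice1"],
            n_background=20,
        )
        path = tmp_path / "design.tsv"
        manifest.write_tsv(path)
        loaded = DesignManifest.read_tsv(path)
        assert loaded.n_spots == manifest.n_spots
        assert [r.probe_id for r in loaded.records] == [
            r.probe_id for r in manifest.records
        ]
        assert [r.unique_seq for r in loaded.records] == [
            r.unique_seq for r in manifest.records
        ]

    def test_ablation_categories_present(self, eice_seed):
        manifest = assemble_design([eice_seed], ablation_seed_ids=["eice1"])
        cats = {r.category for r in manifest.records}
        assert {"seed", "ablation_ets", "ablation_irf"} <= cats
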