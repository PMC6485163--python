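"""Fixture generators: planted truths must be recoverable."""

import numpy as np
import pytest

from ghostabc.dataio import mask_total_length, read_bed_mask, read_manifest, read_vcf
from ghostabc.simulate import desk_fragments
from ghostabc.stats import call_roh
from ghostabc.synthetic import (
    make_admixed_panel,
    make_jsfs_bank,
    make_roh_genome,
    noise_spectrum,
    prior_midpoint,
)
from ghostabc.models import default_priors


def _call_planted(tmp_path):
    geno = read_vcf(tmp_path / "genome.vcf", ["sample1"],
                    read_bed_mask(tmp_path / "mask.bed"))
    mask = read_bed_mask(tmp_path / "mask.bed")
    het = geno.positions[geno.dosages[:, 0] == 1]
    return call_roh({"frag0": het}, mask)


class TestMakeRohGenome:
    def test_planted_segment_recovered(self, tmp_path):
        manifest = make_roh_genome(
            tmp_path,
            planted_segments=[(2_000_000, 4_000_000)],
            genome_length=8_000_000,
            rng_seed=5,
        )
        segs = [s for s in _call_planted(tmp_path) if s.tier == 1.5]
        assert len(segs) == 1
        # bounds within one 1-kbp window of the planted truth
        assert abs(segs[0].start - 2_000_000) <= 1_000 + 1_000
        assert abs(segs[0].end - 4_000_000) <= 2_000
        assert manifest["planted_segments"] == [(2_000_000, 4_000_000)]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_no_planted_segments_no_top_tier_calls(self, tmp_path, seed):
        """1 het/kbp background cannot produce a 1.5 Mbp zero-het run.

        A tier-1.5 call needs ~1500 consecutive empty 1-kbp windows; with
        Poisson(1) hets per window that has probability ~ e^-1500 per
        locus, so any call is a bug.
        """
        make_roh_genome(
            tmp_path / str(seed),
            planted_segments=[],
            genome_length=10_000_000,
            rng_seed=seed,
        )
        segs = _call_planted(tmp_path / str(seed))
        assert [s for s in segs if s.tier == 1.5] == []

    def test_mask_gaps_respected(self, tmp_path):
        make_roh_genome(
            tmp_path,
            planted_segments=[],
            genome_length=1_000_000,
            mask_gaps=[(200_000, 300_000)],
            rng_seed=0,
        )
        mask = read_bed_mask(tmp_path / "mask.bed")
        assert mask_total_length(mask) == 900_000

    def test_empty_mask_empty_vcf(self, tmp_path):
        make_roh_genome(
            tmp_path,
            planted_segments=[],
            genome_length=500_000,
            mask_gaps=[(0, 500_000)],
            rng_seed=0,
        )
        geno = read_vcf(tmp_path / "genome.vcf", ["sample1"])
        assert geno.n_sites == 0
        assert _call_planted(tmp_path) == []

    def test_overlapping_segments_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="overlap"):
            make_roh_genome(
                tmp_path, planted_segments=[(0, 1_000_000), (500_000, 2_000_000)]
            )

    def test_manifest_roundtrip(self, tmp_path):
        make_roh_genome(tmp_path, planted_segments=[(1_000_000, 1_600_000)], rng_seed=3)
        manifest = read_manifest(tmp_path / "manifest.json")
        assert manifest["kind"] == "roh_genome"
        assert manifest["rng_seed"] == 3


class TestEstimatePlantedPulse:
    def test_zero_pulse_estimates_zero(self):
        from ghostabc.synthetic import estimate_planted_pulse

        mean, se = estimate_planted_pulse(
            0.0, 3, fragments=desk_fragments(150, 20_000), rng_seed=6
        )
        assert mean == pytest.approx(0.0, abs=max(3 * se, 0.1))

    def test_full_replacement_estimates_one(self):
        from ghostabc.synthetic import estimate_planted_pulse

        mean, se = estimate_planted_pulse(
            1.0, 3, fragments=desk_fragments(150, 20_000), rng_seed=7
        )
        assert mean == pytest.approx(1.0, abs=max(3 * se, 0.1))


class TestMakeAdmixedPanel:
    def test_same_seed_identical(self):
        frags = desk_fragments(10, 10_000)
        a, _ = make_admixed_panel(0.2, fragments=frags, rng_seed=4)
        b, _ = make_admixed_panel(0.2, fragments=frags, rng_seed=4)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_manifest_records_truth(self):
        _, manifest = make_admixed_panel(
            0.25, fragments=desk_fragments(5, 5_000), rng_seed=1
        )
        assert manifest["alpha"] == 0.25
        assert manifest["rng_seed"] == 1

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            make_admixed_panel(1.5, fragments=desk_fragments(2, 1_000))


@pytest.fixture(scope="module")
def tiny_bank():
    frags = desk_fragments(10, 5_000)
    noise = noise_spectrum(frags, 50)
    return make_jsfs_bank(
        ("A", "B"),
        6,
        frags,
        rng_seed=8,
        noise=noise,
        partition_counts={"train": 4, "reference": 2},
    )


class TestMakeJsfsBank:

    def test_row_counts_and_balance(self, tiny_bank):
        assert tiny_bank.X.shape == (12, 3**7)
        assert (tiny_bank.labels == "A").sum() == 6
        assert (tiny_bank.labels == "B").sum() == 6

    def test_partitions_disjoint_by_provenance(self, tiny_bank):
        train = set(tiny_bank.rows("train"))
        ref = set(tiny_bank.rows("reference"))
        assert train.isdisjoint(ref)
        prov = np.array(tiny_bank.provenance)
        assert set(prov[list(train)]).isdisjoint(prov[list(ref)])

    def test_rows_are_normalized(self, tiny_bank):
        np.testing.assert_allclose(tiny_bank.X.sum(axis=1), 1.0, atol=1e-9)

    def test_params_recorded_per_row(self, tiny_bank):
        col = tiny_bank.param_column("tAMH")
        assert np.isfinite(col).all()
        assert len(tiny_bank.params) == 12


def test_max_ghost_model_mean_spectrum_differs_from_baseline():
    """Model B with pulses at the prior maximum is detectably non-A.

    The L1 distance between mean spectra must exceed the Monte-Carlo noise
    floor measured from two disjoint baseline batches.
    """
    from ghostabc.models import build_model, draw_parameters
    from ghostabc.sfs import compute_jsfs
    from ghostabc.simulate import simulate_fragments

    frags = desk_fragments(150, 20_000)
    n = 14

    def batch(model_id, force, seed0):
        specs = []
        for i in range(n):
            p = draw_parameters(default_priors(model_id), model_id, seed0 + i)
            p.update(force)
            g = simulate_fragments(build_model(model_id, p), frags, seed0 + 500 + i)
            specs.append(compute_jsfs(g).normalize().flatten())
        return np.mean(specs, axis=0)

    force_b = {
        "IntrogressionXf_Kho": 0.1,
        "IntrogressionXf_Mbuti": 0.1,
        "IntrogressionXf_WestAfrica": 0.1,
        "N_XAf": 20_000.0,
        "tAMH_XAf": 790.0,
        "tAMH_Archaics": 950.0,  # keep the forced split inside the topology
    }
    a1 = batch("A", {}, 1000)
    a2 = batch("A", {}, 2000)
    bmax = batch("B", force_b, 3000)
    noise_floor = np.abs(a1 - a2).sum()
    signal = np.abs(bmax - (a1 + a2) / 2).sum()
    assert signal > noise_floor
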