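"""Intensity processing: reading, normalization, replicate aggregation and
background-referenced z-scores."""

import numpy as np
import pandas as pd
import pytest

from nextpbm.array_processing import (
    aggregate_replicates,
    attach_manifest,
    compute_zscores,
    normalize_arrays,
    process_experiment,
    read_intensity_table,
    replicate_agreement,
)
from nextpbm.probe_design import SeedSite, assemble_design


@pytest.fixture(scope="module")
def manifest(small_experiment):
    return small_experiment.manifest


def _raw_table(manifest, rng, base=None, scale=1.0, noise_sd=0.0):
    """Replicate array: shared per-probe log profile plus array-specific
    scale and spot noise."""
    df = manifest.to_dataframe()[["probe_id"]].copy()
    if base is None:
        base = rng.normal(8.0, 1.0, size=len(df))
    noise = rng.normal(0.0, noise_sd, size=len(df)) if noise_sd else 0.0
    df["intensity"] = np.exp(base + noise) * scale
    df["flag"] = "ok"
    return df, base


class TestReadIntensityTable:
    def test_joins_all_rows_of_matching_table(self, tmp_path, manifest):
        df = manifest.to_dataframe()[["probe_id"]].copy()
        df["intensity"] = 1000.0
        path = tmp_path / "a.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_intensity_table(path, manifest)
        assert len(table) == manifest.n_spots
        assert (table["flag"] == "ok").all()

    def test_unknown_probe_ids_dropped_with_warning(self, tmp_path, manifest):
        df = manifest.to_dataframe()[["probe_id"]].head(100).copy()
        df["intensity"] = 500.0
        extra = pd.DataFrame(
            {"probe_id": [f"ghost{i}" for i in range(5)], "intensity": 1.0}
        )
        path = tmp_path / "a.tsv"
        pd.concat([df, extra]).to_csv(path, sep="\t", index=False)
        with pytest.warns(UserWarning, match="5 intensity rows"):
            table = read_intensity_table(path, manifest)
        assert len(table) == 100

    def test_missing_column_reports_found_columns(self, tmp_path, manifest):
        path = tmp_path / "a.tsv"
        pd.DataFrame({"spot": [1], "signal": [2.0]}).to_csv(
            path, sep="\t", index=False
        )
        with pytest.raises(ValueError, match="found.*spot"):
            read_intensity_table(path, manifest)

    def test_negative_intensity_flagged_bad(self, manifest):
        df = manifest.to_dataframe()[["probe_id"]].copy()
        df["intensity"] = 1000.0
        df.loc[0, "intensity"] = -5.0
        df["flag"] = "ok"
        table = attach_manifest(df, manifest)
        assert table.loc[0, "flag"] == "bad"

    def test_genepix_negative_flags_map_to_bad(self, tmp_path, manifest):
        df = manifest.to_dataframe()[["probe_id"]].copy()
        df.columns = ["Name"]
        df["F635 Median"] = 800.0
        df["Flags"] = 0
        df.loc[3, "Flags"] = -100
        path = tmp_path / "a.tsv"
        df.to_csv(path, sep="\t", index=False)
        table = read_intensity_table(
            path, manifest,
            column_map={"probe_id": "Name", "intensity": "F635 Median",
                        "flag": "Flags"},
        )
        assert table.loc[3, "flag"] == "bad"
        assert (table.drop(index=3)["flag"] == "ok").all()


class TestNormalizeArrays:
    def test_pure_scale_factor_removed(self, manifest, rng):
        a, _ = _raw_table(manifest, rng)
        b = a.copy()
        b["intensity"] = b["intensity"] * 2.0
        na, nb = normalize_arrays([a, b])
        assert np.allclose(na["log_intensity"], nb["log_intensity"], atol=1e-9)

    def test_single_array_identity(self, manifest, rng):
        a, _ = _raw_table(manifest, rng)
        (out,) = normalize_arrays([a])
        assert np.allclose(out["log_intensity"], np.log(a["intensity"]))

    def test_idempotent(self, manifest, rng):
        a, base = _raw_table(manifest, rng, noise_sd=0.2)
        b, _ = _raw_table(manifest, rng, base=base, scale=3.0, noise_sd=0.2)
        once = normalize_arrays([a, b])
        again = normalize_arrays([t.copy() for t in once])
        for t1, t2 in zip(once, again):
            assert np.nanmax(np.abs(t1["log_intensity"] - t2["log_intensity"])) < 1e-9

    def test_recovers_planted_gain(self, manifest, rng):
        """Two arrays differing by a known multiplicative log-gain: the
        ratio of fitted slopes recovers the planted value within 1%."""
        a, base = _raw_table(manifest, rng)
        b = a.copy()
        gain, offset = 1.3, 0.7
        b["intensity"] = np.exp(np.log(b["intensity"]) * gain + offset)
        na, nb = normalize_arrays([a, b])
        recovered = nb.attrs["norm_slope"] / na.attrs["norm_slope"]
        assert abs(recovered - gain) / gain < 0.01
        assert np.allclose(na["log_intensity"], nb["log_intensity"], atol=1e-6)

    def test_too_few_shared_probes_fails(self, manifest, rng):
        a, _ = _raw_table(manifest, rng)
        b = a.head(50).copy()
        with pytest.raises(ValueError, match="shares only"):
            normalize_arrays([a, b])


class TestAggregateReplicates:
    def _table_for(self, values, flags=None):
        seed = SeedSite("s1", "ACGTACGTACGTACGTACGT")
        manifest = assemble_design([seed], n_rep=5, max_spots=None)
        df = manifest.to_dataframe()
        df["log_intensity"] = values
        df["intensity"] = np.exp(df["log_intensity"])
        df["flag"] = flags if flags is not None else "ok"
        df["array_id"] = "a1"
        df["channel"] = "c1"
        return df

    def test_median_over_both_orientations(self):
        table = self._table_for([1, 1, 1, 1, 1, 2, 2, 2, 2, 2])
        agg = aggregate_replicates(table)
        assert len(agg) == 1
        assert agg.loc[0, "log_agg"] == 1.5
        assert agg.loc[0, "n_spots_used"] == 10

    def test_flagged_spots_excluded(self):
        flags = ["bad", "bad", "bad"] + ["ok"] * 7
        table = self._table_for(list(range(10)), flags)
        agg = aggregate_replicates(table)
        assert agg.loc[0, "n_spots_used"] == 7
        assert agg.loc[0, "log_agg"] == np.median(range(3, 10))

    def test_matches_numpy_median_oracle(self, rng):
        for _ in range(20):
            values = rng.normal(size=10)
            n_bad = rng.integers(0, 4)
            flags = ["bad"] * n_bad + ["ok"] * (10 - n_bad)
            table = self._table_for(values, flags)
            agg = aggregate_replicates(table)
            expected = np.median(values[n_bad:])
            assert np.isclose(agg.loc[0, "log_agg"], expected)

    def test_permutation_invariant(self, rng):
        values = rng.normal(size=10)
        t1 = self._table_for(values)
        t2 = self._table_for(values[::-1])
        assert np.isclose(
            aggregate_replicates(t1).loc[0, "log_agg"],
            aggregate_replicates(t2).loc[0, "log_agg"],
        )


class TestComputeZscores:
    def _aggregates(self, n_bg=50, rng=None):
        rng = rng or np.random.default_rng(0)
        bg = pd.DataFrame(
            {
                "unique_seq": [f"b{i}" for i in range(n_bg)],
                "log_agg": rng.normal(5.0, 0.5, n_bg),
                "category": "background",
                "n_spots_used": 10,
            }
        )
        return bg

    def test_background_standardized_exactly(self):
        agg = self._aggregates()
        zs = compute_zscores(agg)
        bg_z = zs.loc[zs["category"] == "background", "z"]
        assert abs(bg_z.mean()) < 1e-12
        assert abs(bg_z.std(ddof=1) - 1) < 1e-12

    def test_two_sd_above_mean_scores_two(self):
        agg = self._aggregates()
        bg = agg["log_agg"]
        probe = pd.DataFrame(
            {
                "unique_seq": ["p1"],
                "log_agg": [bg.mean() + 2 * bg.std(ddof=1)],
                "category": ["seed"],
                "n_spots_used": [10],
            }
        )
        zs = compute_zscores(pd.concat([agg, probe], ignore_index=True))
        assert np.isclose(zs.loc[zs["unique_seq"] == "p1", "z"].iloc[0], 2.0)

    def test_affine_invariance(self):
        """Uniform affine transforms of log-intensity are absorbed by the
        background referencing."""
        agg = self._aggregates()
        zs1 = compute_zscores(agg)
        shifted = agg.copy()
        shifted["log_agg"] = 3.0 * shifted["log_agg"] + 7.0
        zs2 = compute_zscores(shifted)
        assert np.allclose(zs1["z"], zs2["z"], atol=1e-9)

    def test_too_few_backgrounds_fails(self):
        agg = self._aggregates(n_bg=10)
        with pytest.raises(ValueError, match="background"):
            compute_zscores(agg)

    def test_degenerate_background_fails(self):
        agg = self._aggregates()
        agg["log_agg"] = 5.0
        with pytest.raises(ValueError, match="zero"):
            compute_zscores(agg)

    def test_planted_boost_recovered(self, small_experiment):
        """Simulated binding sites planted several background-sd above the
        baseline come back with correspondingly high median z."""
        zs = process_experiment(
            small_experiment.manifest, [small_experiment.ivt]
        )
        med_seed = zs.loc[zs["category"] == "seed", "z"].median()
        med_bg = zs.loc[zs["category"] == "background", "z"].median()
        assert med_seed > med_bg + 3.0


class TestReplicateAgreement:
    def _zs(self, z, categories=None):
        return pd.DataFrame(
            {
                "unique_seq": [f"s{i}" for i in range(len(z))],
                "z": z,
                "category": categories or ["seed"] * len(z),
            }
        )

    def test_identical_tables_r_one(self, rng):
        z = rng.normal(size=100)
        stats_out, _ = replicate_agreement(self._zs(z), self._zs(z))
        assert np.isclose(stats_out["pearson_r"], 1.0)

    def test_independent_noise_r_near_zero(self, rng):
        a = self._zs(rng.normal(size=2000))
        b = self._zs(rng.normal(size=2000))
        stats_out, _ = replicate_agreement(a, b)
        assert abs(stats_out["pearson_r"]) < 0.08

    def test_shared_signal_attenuation(self, rng):
        """Shared signal with sd 3x the independent noise sd gives
        r ~ var_sig / (var_sig + var_noise) = 0.9."""
        signal = rng.normal(0, 3.0, size=5000)
        a = self._zs(signal + rng.normal(0, 1.0, size=5000))
        b = self._zs(signal + rng.normal(0, 1.0, size=5000))
        stats_out, _ = replicate_agreement(a, b)
        assert stats_out["pearson_r"] >= 0.88

    def test_too_few_shared_fails(self, rng):
        a = self._zs(rng.normal(size=5))
        with pytest.raises(ValueError, match="shared"):
            replicate_agreement(a, a)
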