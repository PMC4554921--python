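"""Spectral counting, apportionment, normalisation, replicate averaging."""

import numpy as np
import pandas as pd
import pytest

import hermesmap as hm
from hermesmap.errors import ConsistencyError, ParameterError


def make_two_groups():
    g1 = hm.ProteinGroup("G1", frozenset({"G1"}), frozenset({"ua"}), frozenset({"s"}))
    g2 = hm.ProteinGroup("G2", frozenset({"G2"}), frozenset({"ub"}), frozenset({"s"}))
    cls = {
        "ua": ("unique", "G1"),
        "ub": ("unique", "G2"),
        "s": ("shared", frozenset({"G1", "G2"})),
    }
    return [g1, g2], cls


def psms(rows):
    """rows: list of (peptide, n) in sample HB replicate 1."""
    return [
        hm.PSMRecord(pep, "HB", 1, 0.99) for pep, n in rows for _ in range(n)
    ]


class TestCountSpectra:
    def test_unique_psms_accrue_to_their_group(self):
        groups, cls = make_two_groups()
        counts = hm.count_spectra(psms([("ua", 5)]), groups, cls)
        assert counts.raw_unique.loc["G1", "HB:1"] == 5
        assert counts.raw_unique.loc["G2", "HB:1"] == 0
        assert not counts.shared_detail

    def test_shared_psms_pend_apportionment(self):
        groups, cls = make_two_groups()
        counts = hm.count_spectra(psms([("s", 10)]), groups, cls)
        assert counts.raw_unique.values.sum() == 0
        assert counts.raw_shared.loc["G1", "HB:1"] == 10
        assert counts.shared_detail[("s", "HB:1")] == 10

    def test_order_invariance(self):
        groups, cls = make_two_groups()
        records = psms([("ua", 3), ("ub", 2), ("s", 4)])
        a = hm.count_spectra(records, groups, cls)
        b = hm.count_spectra(records[::-1], groups, cls)
        pd.testing.assert_frame_equal(a.raw_unique, b.raw_unique)
        assert a.shared_detail == b.shared_detail

    def test_unclassified_peptide_named(self):
        groups, cls = make_two_groups()
        with pytest.raises(ConsistencyError, match="MYSTERY"):
            hm.count_spectra(psms([("MYSTERY", 1)]), groups, cls)

    def test_dataframe_input_equivalent_to_records(self):
        groups, cls = make_two_groups()
        records = psms([("ua", 3), ("s", 2)])
        frame = pd.DataFrame(
            {"peptide": [r.peptide for r in records],
             "sample": [r.sample for r in records],
             "replicate": [r.replicate for r in records]}
        )
        a = hm.count_spectra(records, groups, cls)
        b = hm.count_spectra(frame, groups, cls)
        pd.testing.assert_frame_equal(a.raw_unique, b.raw_unique)
        assert a.shared_detail == b.shared_detail


class TestApportionShared:
    def test_proportional_formula(self):
        groups, cls = make_two_groups()
        counts = hm.count_spectra(psms([("ua", 4), ("ub", 1), ("s", 10)]), groups, cls)
        app = hm.apportion_shared(counts)
        assert app.loc["G1", "HB:1"] == 4 + 8
        assert app.loc["G2", "HB:1"] == 1 + 2

    def test_zero_unique_fallback_splits_equally(self):
        groups, cls = make_two_groups()
        counts = hm.count_spectra(psms([("s", 6)]), groups, cls)
        app = hm.apportion_shared(counts)
        assert app.loc["G1", "HB:1"] == 3
        assert app.loc["G2", "HB:1"] == 3

    def test_random_instances_conserve_exactly_and_match_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n_groups = int(rng.integers(2, 6))
            reps = [f"G{i}" for i in range(n_groups)]
            groups = []
            cls = {}
            rows = []
            for i, rep in enumerate(reps):
                u = int(rng.integers(0, 6))
                cls[f"u{i}"] = ("unique", rep)
                rows.append((f"u{i}", u))
                groups.append(
                    hm.ProteinGroup(rep, frozenset({rep}), frozenset({f"u{i}"}), frozenset())
                )
            shared_specs = {}
            for j in range(int(rng.integers(1, 4))):
                owners = frozenset(
                    rng.choice(reps, size=int(rng.integers(2, n_groups + 1)), replace=False)
                )
                cls[f"s{j}"] = ("shared", owners)
                s = int(rng.integers(1, 20))
                rows.append((f"s{j}", s))
                shared_specs[f"s{j}"] = (owners, s)
            records = psms(rows)
            counts = hm.count_spectra(records, groups, cls)
            app = hm.apportion_shared(counts)
            # exact conservation
            assert app.values.sum() == len(records)
            # per-peptide proportional recomputation
            expected = counts.raw_unique.copy()
            for pep, (owners, s) in shared_specs.items():
                ow = sorted(owners)
                u = np.array([counts.raw_unique.loc[r, "HB:1"] for r in ow])
                alloc = np.full(len(ow), s / len(ow)) if u.sum() == 0 else s * u / u.sum()
                for r, a in zip(ow, alloc):
                    expected.loc[r, "HB:1"] += a
            assert np.allclose(app.values, expected.values, atol=1e-9)

    def test_peptide_count_mode_uses_distinct_peptides(self):
        g1 = hm.ProteinGroup("G1", frozenset({"G1"}), frozenset({"ua", "ub"}), frozenset({"s"}))
        g2 = hm.ProteinGroup("G2", frozenset({"G2"}), frozenset({"uc"}), frozenset({"s"}))
        cls = {"ua": ("unique", "G1"), "ub": ("unique", "G1"),
               "uc": ("unique", "G2"), "s": ("shared", frozenset({"G1", "G2"}))}
        # G1: 10 spectra over 2 peptides; G2: 1 spectrum over 1 peptide
        records = psms([("ua", 9), ("ub", 1), ("uc", 1), ("s", 6)])
        counts = hm.count_spectra(records, [g1, g2], cls)
        by_spectra = hm.apportion_shared(counts, mode="spectra")
        by_peptides = hm.apportion_shared(counts, mode="peptides")
        assert by_spectra.loc["G1", "HB:1"] == 10 + 6 * 10 / 11
        assert by_peptides.loc["G1", "HB:1"] == 10 + 6 * 2 / 3

    def test_unknown_mode_rejected(self):
        groups, cls = make_two_groups()
        counts = hm.count_spectra(psms([("ua", 1)]), groups, cls)
        with pytest.raises(ParameterError):
            hm.apportion_shared(counts, mode="intensity")


class TestPercentTotal:
    def test_single_group_is_100(self):
        app = pd.DataFrame({"HB:1": [7.0]}, index=["G1"])
        assert hm.percent_total(app).loc["G1", "HB:1"] == 100.0

    def test_simple_split(self):
        app = pd.DataFrame({"HB:1": [30.0, 70.0]}, index=["G1", "G2"])
        assert list(hm.percent_total(app)["HB:1"]) == [30.0, 70.0]

    def test_columns_sum_to_100(self):
        rng = np.random.default_rng(3)
        app = pd.DataFrame(rng.random((20, 6)) * 50,
                           index=[f"G{i}" for i in range(20)],
                           columns=[f"F{j}:1" for j in range(6)])
        assert np.allclose(hm.percent_total(app).sum(axis=0), 100.0, atol=1e-9)

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        app = pd.DataFrame(rng.integers(1, 100, (5, 3)).astype(float),
                           index=list("abcde"), columns=["F:1", "F:2", "F:3"])
        pd.testing.assert_frame_equal(hm.percent_total(app), hm.percent_total(2 * app))

    def test_empty_sample_named(self):
        app = pd.DataFrame({"HB:1": [1.0], "TG:1": [0.0]}, index=["G1"])
        with pytest.raises(ParameterError, match="TG:1"):
            hm.percent_total(app)


class TestAverageReplicates:
    def test_mean_and_sample_sd(self):
        percent = pd.DataFrame({"HB:1": [10.0], "HB:2": [20.0], "HB:3": [30.0]},
                               index=["G1"])
        mean, sd = hm.average_replicates(percent)
        assert mean.loc["G1", "HB"] == 20.0
        assert sd.loc["G1", "HB"] == 10.0

    def test_single_replicate_sd_zero(self):
        percent = pd.DataFrame({"HB:1": [42.0]}, index=["G1"])
        mean, sd = hm.average_replicates(percent)
        assert mean.loc["G1", "HB"] == 42.0
        assert sd.loc["G1", "HB"] == 0.0

    def test_profile_recomputable_from_percent_columns(self):
        rng = np.random.default_rng(6)
        cols = [f"{f}:{r}" for f in ("HB", "TG") for r in (1, 2, 3)]
        percent = pd.DataFrame(rng.random((4, 6)), index=list("wxyz"), columns=cols)
        mean, sd = hm.average_replicates(percent, ("HB", "TG"))
        for f in ("HB", "TG"):
            block = percent[[c for c in cols if c.startswith(f)]]
            assert np.allclose(mean[f], block.mean(axis=1))
            assert np.allclose(sd[f], block.std(axis=1, ddof=1))


class TestQuantifyPipeline:
    def test_conservation_and_drop_report(self, small_proteome):
        accs = [a for a, _ in small_proteome.proteins]
        ab, _ = hm.planted_abundance(accs, ("HB", "TG"), "HB", 2, 2, seed=1)
        design = hm.FractionDesign(("HB", "TG"), ab, 2, 500, seed=1)
        tables = hm.generate_psm_tables(small_proteome, design)
        df = pd.concat(tables.values(), ignore_index=True)
        pmap, _ = hm.map_peptides(set(df.peptide), small_proteome.proteins)
        groups = hm.infer_minimal_set(pmap)
        cls = hm.classify_peptides(groups)
        qm = hm.quantify_pipeline(df, groups, cls, fraction_order=("HB", "TG"))
        totals = df.groupby(df["sample"] + ":" + df["replicate"].astype(str)).size()
        for col in qm.apportioned.columns:
            assert qm.apportioned[col].sum() == totals[col]
        assert np.allclose(qm.percent.sum(axis=0), 100.0, atol=1e-9)
        assert set(qm.dropped_groups).isdisjoint(qm.apportioned.index)
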