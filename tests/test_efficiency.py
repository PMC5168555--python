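"""Efficiency ratio, confidence rule, pooling, pairing and output tables."""

import math

import pandas as pd
import pytest

from spliceff.annotation import FIVE_PRIME, THREE_PRIME
from spliceff.efficiency import (
    EfficiencyRecord,
    WorkflowConfig,
    efficiency_scatterplot,
    pool_samples,
    relative_efficiency,
    splicing_efficiency,
    write_efficiency_tables,
    write_relative_table,
)

KEY = ("chrI", 100, 200, "+")


def _rec(eff, confident, sample="s", trans=10, cov=10, key=KEY, site=FIVE_PRIME):
    return EfficiencyRecord(
        intron_key=key,
        site=site,
        sample_or_group=sample,
        transread_count=trans,
        terminal_coverage=cov,
        efficiency=eff,
        confident=confident,
        gene_id="g1",
    )


class TestSplicingEfficiency:
    @pytest.mark.parametrize(
        "trans,cov,efficiency,confident",
        [
            (10, 10, 1.0, True),
            (5, 5, 1.0, True),  # threshold is inclusive
            (9, 4, 2.25, False),
            (4, 5, 0.8, False),
            (4, 4, 1.0, False),
            (0, 50, 0.0, False),
        ],
    )
    def test_ratio_and_confidence(self, trans, cov, efficiency, confident):
        eff, conf = splicing_efficiency(trans, cov)
        assert eff == pytest.approx(efficiency)
        assert conf is confident

    def test_zero_coverage_is_undefined_never_confident(self):
        eff, conf = splicing_efficiency(7, 0)
        assert math.isnan(eff) and not conf

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            splicing_efficiency(-1, 5)

    def test_custom_thresholds(self):
        assert splicing_efficiency(3, 3, min_transreads=3, min_coverage=3)[1]


class TestPooling:
    def test_counts_sum_elementwise(self):
        per_sample = {"a": {KEY: 3}, "b": {KEY: 4}}
        assert pool_samples(per_sample, ["a", "b"]) == {KEY: 7}

    def test_single_sample_group_is_identity(self):
        per_sample = {"a": {KEY: 3, "other": 1}}
        assert pool_samples(per_sample, ["a"]) == per_sample["a"]

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            pool_samples({"a": {}}, [])

    def test_pooled_counts_can_reach_confidence_jointly(self):
        trans = pool_samples({"a": {KEY: 3}, "b": {KEY: 4}}, ["a", "b"])
        cov = pool_samples({"a": {KEY: 5}, "b": {KEY: 7}}, ["a", "b"])
        eff, conf = splicing_efficiency(trans[KEY], cov[KEY])
        assert conf  # 7/12 although each replicate alone was below threshold
        assert eff == pytest.approx(7 / 12)


class TestRelativeEfficiency:
    def test_identical_records_give_one(self):
        rec = _rec(0.5, True)
        assert relative_efficiency(rec, rec).relative_efficiency == pytest.approx(1.0)

    def test_impaired_test_sample(self):
        rel = relative_efficiency(_rec(0.1, True, "mut"), _rec(0.9, True, "wt"))
        assert rel.relative_efficiency == pytest.approx(0.1 / 0.9)
        assert rel.pair_id == ("mut", "wt")

    @pytest.mark.parametrize(
        "test_conf,ref_conf,ref_eff",
        [(True, False, 0.5), (False, True, 0.5), (True, True, 0.0)],
    )
    def test_undefined_when_not_confident_or_zero_reference(
        self, test_conf, ref_conf, ref_eff
    ):
        rel = relative_efficiency(
            _rec(0.5, test_conf, "mut"), _rec(ref_eff, ref_conf, "wt")
        )
        assert math.isnan(rel.relative_efficiency)

    def test_mismatched_intron_rejected(self):
        other = ("chrII", 5, 50, "-")
        with pytest.raises(ValueError):
            relative_efficiency(_rec(0.5, True), _rec(0.5, True, key=other))

    def test_mismatched_site_rejected(self):
        with pytest.raises(ValueError):
            relative_efficiency(
                _rec(0.5, True), _rec(0.5, True, site=THREE_PRIME)
            )


class TestTables:
    def test_conf_table_contains_exactly_confident_rows(self, tmp_path):
        keys = [("chrI", s, s + 100, "+") for s in (0, 300, 600)]
        records = [
            _rec(1.0, True, key=keys[0]),
            _rec(0.4, False, key=keys[1]),
            _rec(float("nan"), False, key=keys[2], cov=0),
        ]
        conf, full = write_efficiency_tables(
            records, tmp_path / "conf.csv", tmp_path / "all.csv"
        )
        assert len(conf) == 1 and len(full) == 3
        on_disk = pd.read_csv(tmp_path / "conf.csv")
        assert len(on_disk) == 1
        assert on_disk.iloc[0]["start"] == 0

    def test_undefined_efficiency_written_as_na(self, tmp_path):
        records = [_rec(float("nan"), False, cov=0)]
        write_efficiency_tables(records, tmp_path / "c.csv", tmp_path / "a.csv")
        line = (tmp_path / "a.csv").read_text().splitlines()[1]
        assert ",NA," in line

    def test_no_confident_records_gives_header_only(self, tmp_path):
        write_efficiency_tables(
            [_rec(0.4, False)], tmp_path / "c.csv", tmp_path / "a.csv"
        )
        assert len((tmp_path / "c.csv").read_text().splitlines()) == 1

    def test_relative_table_keeps_defined_rows(self, tmp_path):
        keys = [("chrI", s, s + 100, "+") for s in (0, 300)]
        records = [
            relative_efficiency(
                _rec(0.2, True, "mut", key=keys[0]), _rec(0.8, True, "wt", key=keys[0])
            ),
            relative_efficiency(
                _rec(0.2, True, "mut", key=keys[1]), _rec(0.8, False, "wt", key=keys[1])
            ),
        ]
        table = write_relative_table(records, tmp_path / "rel.csv")
        assert len(table) == 1
        assert table.iloc[0]["relative_efficiency"] == pytest.approx(0.25)


class TestScatterplot:
    def _records(self, sample, effs, confident=True):
        return [
            _rec(e, confident, sample, key=("chrI", 100 * i, 100 * i + 80, "+"))
            for i, e in enumerate(effs)
        ]

    def test_pdf_written_with_marker_partition(self, tmp_path):
        ref = self._records("wt", [0.5] * 10) + self._records(
            "wt", [0.5] * 5, confident=False
        )
        # fix duplicate keys for the low-confidence batch
        for i, r in enumerate(ref[10:]):
            r.intron_key = ("chrI", 2000 + 100 * i, 2080 + 100 * i, "+")
        test = [
            _rec(r.efficiency / 2, r.confident, "mut", key=r.intron_key) for r in ref
        ]
        out = efficiency_scatterplot(test, ref, FIVE_PRIME, tmp_path / "sc.pdf")
        assert out.exists() and out.stat().st_size > 0

    def test_halved_counts_displace_points_below_diagonal(self, tmp_path):
        """Halving every transread count halves each efficiency estimate."""
        ref = [
            _rec(t / 20, True, "wt", trans=t, cov=20,
                 key=("chrI", 100 * i, 100 * i + 80, "+"))
            for i, t in enumerate([8, 10, 20, 40])
        ]
        test = [
            _rec(r.transread_count // 2 / r.terminal_coverage, True, "mut",
                 trans=r.transread_count // 2, cov=r.terminal_coverage,
                 key=r.intron_key)
            for r in ref
        ]
        for t, r in zip(test, ref):
            assert t.efficiency < r.efficiency
        out = efficiency_scatterplot(test, ref, FIVE_PRIME, tmp_path / "below.pdf")
        assert out.exists()

    def test_empty_plot_still_produced_with_warning(self, tmp_path):
        with pytest.warns(UserWarning, match="no plottable"):
            out = efficiency_scatterplot([], [], FIVE_PRIME, tmp_path / "empty.pdf")
        assert out.exists()


class TestWorkflowConfig:
    def test_strandedness_is_mandatory_and_validated(self):
        with pytest.raises(ValueError, match="strandedness"):
            WorkflowConfig(strandedness="none")

    def test_groups_must_reference_declared_samples(self):
        with pytest.raises(ValueError, match="undeclared"):
            WorkflowConfig(
                strandedness="reverse",
                samples={"a": "a.sam"},
                sample_groups={"g": ["a", "b"]},
            )

    def test_pairs_may_reference_groups(self):
        cfg = WorkflowConfig(
            strandedness="reverse",
            samples={"a": "a.sam", "b": "b.sam"},
            sample_groups={"g": ["a", "b"]},
            sample_pairs=[("a", "g")],
        )
        assert cfg.sample_pairs == [("a", "g")]

    def test_yaml_round_trip(self, tmp_path):
        (tmp_path / "cfg.yaml").write_text(
            "strandedness: reverse\n"
            "samples:\n  wt: wt.sam\n  mut: mut.sam\n"
            "sample_pairs:\n- [mut, wt]\n"
            "min_anchor: 6\n"
        )
        cfg = WorkflowConfig.from_yaml(tmp_path / "cfg.yaml")
        assert cfg.min_anchor == 6
        assert cfg.sample_pairs == [("mut", "wt")]
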