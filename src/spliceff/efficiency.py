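"""Splicing-efficiency computation, confidence filtering and sample pairing.

For each intron the efficiency at a splice site is the ratio of spliced to
unspliced evidence::

    efficiency_5' = transread_count / coverage(first intron base)
    efficiency_3' = transread_count / coverage(last intron base)

Transreads arise only from spliced mRNA; reads covering the single terminal
base arise only from unspliced pre-mRNA, because split-read counting
excludes the transreads themselves.  The two sites proxy the first and
second catalytic steps of splicing.  Library size cancels inside a sample,
so no normalisation is applied.

Low-coverage junctions give unstable ratios, so a record is *confident*
only when transread count and terminal-base coverage are both at least 5
(configurable).  Replicates of one genotype may be pooled by summing raw
counts before the ratio is taken.  Sample pairs (e.g. mutant vs wild type)
yield relative efficiencies, defined only where both members are confident.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, TypeVar, Union

import pandas as pd

from .annotation import (
    FIVE_PRIME,
    THREE_PRIME,
    IntronKey,
    IntronRecord,
    intron_terminal_bases,
)

SITES = (FIVE_PRIME, THREE_PRIME)
_SITE_TAG = {FIVE_PRIME: "5ss", THREE_PRIME: "3ss"}

K = TypeVar("K")


@dataclass
class EfficiencyRecord:
    """Splicing efficiency of one intron at one site for one sample/group.

    ``efficiency`` is NaN (reported as NA) when terminal coverage is zero;
    such records can never be confident.
    """

    intron_key: IntronKey
    site: str
    sample_or_group: str
    transread_count: int
    terminal_coverage: int
    efficiency: float
    confident: bool
    gene_id: Optional[str] = None


@dataclass
class RelativeEfficiencyRecord:
    """Test/reference efficiency ratio at one intron and site.

    NaN unless both members are confident and the reference efficiency is
    positive.
    """

    intron_key: IntronKey
    site: str
    pair_id: tuple[str, str]  # (test, reference)
    relative_efficiency: float
    test_efficiency: float = math.nan
    reference_efficiency: float = math.nan
    gene_id: Optional[str] = None


@dataclass
class WorkflowConfig:
    """All knobs of the splicing-efficiency workflow.

    ``strandedness`` has no default on purpose: it must match the library
    protocol or every count silently measures the antisense strand.
    ``sample_groups`` pools replicates by summing raw counts;
    ``sample_pairs`` lists (test, reference) comparisons whose members may
    be sample ids or group ids.
    """

    strandedness: str
    samples: dict[str, str] = field(default_factory=dict)  # sample -> SAM/BAM
    annotation: Optional[str] = None  # GTF path
    output_dir: Optional[str] = None
    min_mapq: int = 10
    min_intron: int = 20
    max_intron: int = 10000
    min_anchor: int = 8
    min_transreads: int = 5
    min_coverage: int = 5
    sample_groups: dict[str, list[str]] = field(default_factory=dict)
    sample_pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strandedness not in ("forward", "reverse"):
            raise ValueError(
                f"strandedness must be 'forward' or 'reverse', "
                f"got {self.strandedness!r}"
            )
        for name in (
            "min_mapq",
            "min_intron",
            "max_intron",
            "min_anchor",
            "min_transreads",
            "min_coverage",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for group, members in self.sample_groups.items():
            unknown = set(members) - set(self.samples)
            if self.samples and unknown:
                raise ValueError(
                    f"group {group!r} references undeclared samples {sorted(unknown)}"
                )
        units = set(self.samples) | set(self.sample_groups)
        self.sample_pairs = [tuple(p) for p in self.sample_pairs]
        for test, ref in self.sample_pairs:
            if self.samples and {test, ref} - units:
                raise ValueError(
                    f"pair ({test}, {ref}) references undeclared samples/groups"
                )

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "WorkflowConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def splicing_efficiency(
    transread_count: int,
    terminal_coverage: int,
    min_transreads: int = 5,
    min_coverage: int = 5,
) -> tuple[float, bool]:
    """Return (efficiency, confident) for one splice site.

    Efficiency is ``transread_count / terminal_coverage``, NaN when the
    coverage is zero.  The record is confident only when both counts reach
    their thresholds (inclusive); a NaN efficiency is never confident.
    """
    if transread_count < 0 or terminal_coverage < 0:
        raise ValueError("read counts must be non-negative")
    if terminal_coverage == 0:
        return math.nan, False
    efficiency = transread_count / terminal_coverage
    confident = transread_count >= min_transreads and terminal_coverage >= min_coverage
    return efficiency, confident


def pool_samples(
    per_sample_counts: Mapping[str, Mapping[K, int]],
    group: Sequence[str],
) -> dict[K, int]:
    """Sum counts element-wise across a group's samples.

    Pooling happens on raw counts *before* any ratio, so replicates that
    are individually below threshold can jointly clear it.
    """
    if not group:
        raise ValueError("cannot pool an empty sample group")
    pooled: dict[K, int] = {}
    for sample in group:
        for key, count in per_sample_counts[sample].items():
            pooled[key] = pooled.get(key, 0) + count
    return pooled


def relative_efficiency(
    test: EfficiencyRecord, reference: EfficiencyRecord
) -> RelativeEfficiencyRecord:
    """Ratio of test to reference efficiency at one intron and site.

    Defined only when both records are confident and the reference
    efficiency is positive; otherwise NaN.
    """
    if test.intron_key != reference.intron_key or test.site != reference.site:
        raise ValueError(
            "relative efficiency requires matching intron and site: "
            f"{test.intron_key}/{test.site} vs {reference.intron_key}/{reference.site}"
        )
    if test.confident and reference.confident and reference.efficiency > 0:
        value = test.efficiency / reference.efficiency
    else:
        value = math.nan
    return RelativeEfficiencyRecord(
        intron_key=test.intron_key,
        site=test.site,
        pair_id=(test.sample_or_group, reference.sample_or_group),
        relative_efficiency=value,
        test_efficiency=test.efficiency,
        reference_efficiency=reference.efficiency,
        gene_id=test.gene_id or reference.gene_id,
    )


def efficiency_records(
    introns: Sequence[IntronRecord],
    transread_counts: Mapping[tuple[str, int, int], int],
    terminal_coverage: Mapping,
    sample_or_group: str,
    site: str,
    min_transreads: int = 5,
    min_coverage: int = 5,
) -> list[EfficiencyRecord]:
    """Assemble per-intron efficiency records for one sample/group and site.

    ``transread_counts`` is keyed by junction coordinates (chrom, start,
    end); ``terminal_coverage`` by :class:`~spliceff.annotation.TerminalBase`.
    Every intron yields a record (zero counts included) so that the "_all"
    table is a complete census.
    """
    if site not in SITES:
        raise ValueError(f"site must be one of {SITES}, got {site!r}")
    terminal = {
        (tb.intron_key, tb.which_end): tb
        for tb in intron_terminal_bases(introns)
    }
    out = []
    for intron in introns:
        trans = transread_counts.get((intron.chrom, intron.start, intron.end), 0)
        tb = terminal[(intron.key, site)]
        cov = terminal_coverage.get(tb, 0)
        eff, confident = splicing_efficiency(trans, cov, min_transreads, min_coverage)
        out.append(
            EfficiencyRecord(
                intron_key=intron.key,
                site=site,
                sample_or_group=sample_or_group,
                transread_count=trans,
                terminal_coverage=cov,
                efficiency=eff,
                confident=confident,
                gene_id=intron.gene_id,
            )
        )
    return out


def efficiency_frame(records: Iterable[EfficiencyRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.intron_key[0],
            "start": r.intron_key[1],
            "end": r.intron_key[2],
            "strand": r.intron_key[3],
            "gene_id": r.gene_id,
            "site": r.site,
            "sample": r.sample_or_group,
            "transreads": r.transread_count,
            "coverage": r.terminal_coverage,
            "efficiency": r.efficiency,
            "confident": r.confident,
        }
        for r in records
    ]
    columns = [
        "chrom", "start", "end", "strand", "gene_id", "site", "sample",
        "transreads", "coverage", "efficiency", "confident",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_efficiency_tables(
    records: Iterable[EfficiencyRecord],
    conf_path: Union[str, Path],
    all_path: Union[str, Path],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write the confident-only and complete efficiency CSVs for one site.

    The "_conf" table contains exactly the confident rows; the companion
    "_all" table carries every record with its confidence flag.  Undefined
    efficiencies are written as NA.
    """
    table = efficiency_frame(records)
    conf = table[table["confident"]].reset_index(drop=True)
    conf.to_csv(conf_path, index=False, na_rep="NA")
    table.to_csv(all_path, index=False, na_rep="NA")
    return conf, table


def relative_frame(records: Iterable[RelativeEfficiencyRecord]) -> pd.DataFrame:
    rows = [
        {
            "chrom": r.intron_key[0],
            "start": r.intron_key[1],
            "end": r.intron_key[2],
            "strand": r.intron_key[3],
            "gene_id": r.gene_id,
            "site": r.site,
            "test": r.pair_id[0],
            "reference": r.pair_id[1],
            "test_efficiency": r.test_efficiency,
            "reference_efficiency": r.reference_efficiency,
            "relative_efficiency": r.relative_efficiency,
        }
        for r in records
    ]
    columns = [
        "chrom", "start", "end", "strand", "gene_id", "site", "test",
        "reference", "test_efficiency", "reference_efficiency",
        "relative_efficiency",
    ]
    return pd.DataFrame(rows, columns=columns)


def write_relative_table(
    records: Iterable[RelativeEfficiencyRecord],
    conf_path: Union[str, Path],
) -> pd.DataFrame:
    """Write defined (both members confident) relative efficiencies as CSV."""
    table = relative_frame(records)
    conf = table[table["relative_efficiency"].notna()].reset_index(drop=True)
    conf.to_csv(conf_path, index=False, na_rep="NA")
    return conf


def efficiency_scatterplot(
    test_records: Sequence[EfficiencyRecord],
    reference_records: Sequence[EfficiencyRecord],
    site: str,
    path: Union[str, Path],
    test_label: str = "test",
    reference_label: str = "reference",
) -> Path:
    """Scatter reference vs test efficiency per intron, written as PDF.

    Confident introns (both members) are drawn filled, low-confidence ones
    open.  Axes are log10-scaled; introns with an undefined or zero
    efficiency on either axis are excluded from the plot and their number
    reported in the margin text.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import warnings

    ref_by_key = {r.intron_key: r for r in reference_records if r.site == site}
    pairs = [
        (t, ref_by_key[t.intron_key])
        for t in test_records
        if t.site == site and t.intron_key in ref_by_key
    ]
    plottable = [
        (t, r)
        for t, r in pairs
        if t.efficiency > 0 and r.efficiency > 0  # NaN comparisons are False
    ]
    excluded = len(pairs) - len(plottable)

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    if not plottable:
        warnings.warn(f"no plottable points for {path}; writing an empty plot")
    full = [(r.efficiency, t.efficiency) for t, r in plottable if t.confident and r.confident]
    open_ = [(r.efficiency, t.efficiency) for t, r in plottable if not (t.confident and r.confident)]
    if full:
        xs, ys = zip(*full)
        ax.scatter(xs, ys, s=18, facecolors="black", edgecolors="black",
                   label="confident")
    if open_:
        xs, ys = zip(*open_)
        ax.scatter(xs, ys, s=18, facecolors="none", edgecolors="grey",
                   label="low confidence")
    if plottable:
        ax.set_xscale("log")
        ax.set_yscale("log")
        lims = ax.get_xlim() + ax.get_ylim()
        lo, hi = min(lims), max(lims)
        ax.plot([lo, hi], [lo, hi], lw=0.6, color="grey", zorder=0)
        ax.legend(frameon=False, fontsize=7)
    tag = _SITE_TAG[site]
    ax.set_xlabel(f"{reference_label} efficiency ({tag})")
    ax.set_ylabel(f"{test_label} efficiency ({tag})")
    ax.set_title(f"Splicing efficiency, {tag}", fontsize=10)
    if excluded:
        fig.text(
            0.99, 0.01,
            f"{excluded} introns excluded (zero/undefined efficiency)",
            ha="right", fontsize=6,
        )
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, format="pdf")
    plt.close(fig)
    return path
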