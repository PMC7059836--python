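"""Evaluation of a call set against a gold standard.

Four evaluations, each reported per contig with an unweighted-mean summary
row (chrX is excluded from summaries by default, since it is evaluated on
pseudo-autosomal regions only and is not comparable to autosomes):

* site concordance within high-confidence regions (TP / FN / FP and their
  percentages),
* switch-error rate of phased heterozygous genotypes,
* attribution of false negatives to the filter labels that removed them,
* stratification of call sets by region class (novel vs existing sequence).

Reports carry full precision internally; the TSV writers round rates to two
decimals, matching the conventional table layout (one contig per row plus
an AVG row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .filters import LabeledSites, label_against_gold
from .model import CallSet, RegionSet, SiteKey

__all__ = [
    "ConcordanceReport",
    "SwitchErrorReport",
    "AttributionReport",
    "StratificationReport",
    "concordance",
    "switch_error",
    "fn_attribution",
    "stratify_regions",
    "aggregate_report",
]

DEFAULT_EXCLUDE = ("chrX",)


def aggregate_report(rows: pd.DataFrame, exclude: Sequence[str] = ()) -> pd.Series:
    """Unweighted arithmetic mean of each numeric column over included contigs.

    This is the AVG-row convention: the mean of the per-contig values, not
    the pooled ratio.  Raises when every row is excluded.
    """
    included = rows.loc[[c for c in rows.index if c not in set(exclude)]]
    if included.empty:
        raise ValueError("all rows excluded from the aggregate")
    return included.mean(numeric_only=True)


def _write_tsv(rows: pd.DataFrame, avg: pd.Series, path: str) -> None:
    out = rows.copy()
    out.loc["AVG"] = avg
    out = out.round(2)
    out.to_csv(path, sep="\t", index_label="contig")


@dataclass
class ConcordanceReport:
    """Per-contig TP/FN/FP counts with derived percentages.

    ``pct_shared`` and ``pct_gold_only`` are relative to the gold total
    (tp + fn); ``pct_query_only`` is relative to the query total (tp + fp).
    """

    rows: pd.DataFrame
    exclude: tuple = DEFAULT_EXCLUDE

    COLUMNS = (
        "tp",
        "pct_shared",
        "fn",
        "pct_gold_only",
        "fp",
        "pct_query_only",
        "total_gold",
        "total_query",
    )

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, tuple[int, int, int]],
        exclude: Sequence[str] = DEFAULT_EXCLUDE,
    ) -> "ConcordanceReport":
        """Build a report from per-contig (tp, fn, fp) counts."""
        records = {}
        for contig, (tp, fn, fp) in counts.items():
            total_gold = tp + fn
            total_query = tp + fp
            records[contig] = {
                "tp": tp,
                "pct_shared": 100.0 * tp / total_gold if total_gold else np.nan,
                "fn": fn,
                "pct_gold_only": 100.0 * fn / total_gold if total_gold else np.nan,
                "fp": fp,
                "pct_query_only": 100.0 * fp / total_query if total_query else np.nan,
                "total_gold": total_gold,
                "total_query": total_query,
            }
        rows = pd.DataFrame.from_dict(records, orient="index").reindex(columns=cls.COLUMNS)
        return cls(rows=rows, exclude=tuple(exclude))

    def aggregate(self) -> pd.Series:
        return aggregate_report(self.rows, exclude=self.exclude)

    def write_tsv(self, path: str) -> None:
        _write_tsv(self.rows, self.aggregate(), path)


def concordance(
    query: CallSet,
    gold: CallSet,
    regions: RegionSet,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> ConcordanceReport:
    """Site concordance of ``query`` against ``gold`` within confidence regions.

    Both inputs must be normalized and biallelic; the caller pre-selects the
    variant class (SNV or INDEL) when a class-specific table is wanted.
    Contigs with no gold or query sites inside the regions get undefined
    (NaN) percentages.
    """
    labels = label_against_gold(query, gold, regions)
    contigs = [
        c
        for c in gold.contigs + [c for c in query.contigs if c not in gold.contigs]
        if any(k.contig == c for k in labels.tp_keys | labels.fn_keys | labels.fp_keys)
    ]
    counts = {}
    for contig in contigs:
        tp = sum(1 for k in labels.tp_keys if k.contig == contig)
        fn = sum(1 for k in labels.fn_keys if k.contig == contig)
        fp = sum(1 for k in labels.fp_keys if k.contig == contig)
        counts[contig] = (tp, fn, fp)
    return ConcordanceReport.from_counts(counts, exclude=exclude)


@dataclass
class SwitchErrorReport:
    """Per-contig assessed pair counts, switch counts and rates (percent)."""

    rows: pd.DataFrame
    exclude: tuple = DEFAULT_EXCLUDE

    def aggregate(self) -> pd.Series:
        return aggregate_report(self.rows, exclude=self.exclude)

    def write_tsv(self, path: str) -> None:
        _write_tsv(self.rows, self.aggregate(), path)


def switch_error(
    truth: CallSet,
    pred: CallSet,
    sample: str,
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> SwitchErrorReport:
    """Switch-error rate of predicted phasing against true haplotypes.

    Assessable sites are those present in both call sets where ``sample`` is
    heterozygous with the same unphased genotype and phased in both.  Each
    assessable site has a relative orientation (predicted first haplotype
    matches the true first haplotype, or is flipped); a switch is an
    orientation change between consecutive assessable sites on a contig.
    The rate is ``100 * switches / (assessable - 1)``.  Phase is relative: a
    global haplotype flip yields zero switches.  Contigs with fewer than two
    assessable sites get an undefined (NaN) rate.
    """
    if sample not in truth.samples or sample not in pred.samples:
        raise ValueError(f"sample {sample!r} missing from one of the call sets")
    jt = truth.samples.index(sample)
    jp = pred.samples.index(sample)
    truth_gt = {s.key(): truth.genotypes[i][jt] for i, s in enumerate(truth.sites)}
    pred_gt = {s.key(): pred.genotypes[i][jp] for i, s in enumerate(pred.sites)}

    per_contig: dict[str, list[tuple[int, bool]]] = {}
    for key, tg in truth_gt.items():
        pg = pred_gt.get(key)
        if pg is None:
            continue
        if not (tg.is_het() and pg.is_het() and tg.phased and pg.phased):
            continue
        if tg.unphased_key() != pg.unphased_key():
            continue
        per_contig.setdefault(key.contig, []).append((key.pos, pg.a == tg.a))

    records = {}
    for contig in truth.contigs:
        sites = sorted(per_contig.get(contig, []))
        if not sites:
            continue
        orientations = [o for _, o in sites]
        pairs = len(orientations) - 1
        switches = sum(
            1 for i in range(pairs) if orientations[i] != orientations[i + 1]
        )
        records[contig] = {
            "pairs": pairs,
            "switches": switches,
            "rate": 100.0 * switches / pairs if pairs > 0 else np.nan,
        }
    if not records:
        raise ValueError(f"no assessable phased heterozygous sites for {sample!r}")
    rows = pd.DataFrame.from_dict(records, orient="index")
    return SwitchErrorReport(rows=rows, exclude=tuple(exclude))


@dataclass
class AttributionReport:
    """False negatives per contig broken down by the filter label that removed them.

    ``pct_explained`` is 100 times the attributed count (summed over the
    tracked labels) divided by the contig's FN count.
    """

    rows: pd.DataFrame
    label_names: tuple
    exclude: tuple = DEFAULT_EXCLUDE

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[str, Sequence[int]],
        label_names: Sequence[str],
        exclude: Sequence[str] = DEFAULT_EXCLUDE,
    ) -> "AttributionReport":
        """Build from per-contig rows ``(fn_count, label1_count, label2_count, ...)``."""
        records = {}
        for contig, row in counts.items():
            fn = row[0]
            attributed = row[1:]
            if sum(attributed) > fn:
                raise ValueError(f"{contig}: attributed count exceeds FN count")
            rec = {"fn": fn}
            rec.update({lab: n for lab, n in zip(label_names, attributed)})
            rec["pct_explained"] = 100.0 * sum(attributed) / fn if fn else np.nan
            records[contig] = rec
        rows = pd.DataFrame.from_dict(records, orient="index")
        return cls(rows=rows, label_names=tuple(label_names), exclude=tuple(exclude))

    def aggregate(self) -> pd.Series:
        return aggregate_report(self.rows, exclude=self.exclude)

    def write_tsv(self, path: str) -> None:
        _write_tsv(self.rows, self.aggregate(), path)


def fn_attribution(
    labels: LabeledSites,
    filtered_query: CallSet,
    label_names: Sequence[str],
    exclude: Sequence[str] = DEFAULT_EXCLUDE,
) -> AttributionReport:
    """Attribute false negatives to the filter labels that discarded them.

    ``filtered_query`` is the pre-selection call set still carrying its soft
    filter labels; ``labels`` comes from comparing the post-selection call
    set against the gold standard.  An FN site found in ``filtered_query``
    is tallied once per tracked label it carries.
    """
    by_key = {s.key(): s for s in filtered_query.sites}
    contigs = sorted({k.contig for k in labels.fn_keys})
    counts: dict[str, list[int]] = {}
    for contig in contigs:
        fn_keys = [k for k in labels.fn_keys if k.contig == contig]
        per_label = [0] * len(label_names)
        for k in fn_keys:
            site = by_key.get(k)
            if site is None:
                continue
            for i, lab in enumerate(label_names):
                if lab in site.filters:
                    per_label[i] += 1
        counts[contig] = [len(fn_keys), *per_label]
    return AttributionReport.from_counts(counts, label_names, exclude=exclude)


@dataclass
class StratificationReport:
    """Call-set site counts stratified by region class (novel vs existing).

    ``counts.loc[cls, label]`` is the number of sites of call set ``label``
    in class ``cls``; ``shares`` holds each call set's percentage of the
    class total.  ``novel_tp_pct`` (optional) gives per-contig TP
    percentages against a gold standard within the novel class.
    """

    counts: pd.DataFrame
    shares: pd.DataFrame
    novel_tp_pct: Optional[pd.DataFrame] = None

    @classmethod
    def from_counts(
        cls,
        counts: pd.DataFrame,
        novel_tp_pct: Optional[pd.DataFrame] = None,
    ) -> "StratificationReport":
        """Derive the share percentages from a per-class count table."""
        totals = counts.sum(axis=1)
        shares = counts.div(totals.replace(0, np.nan), axis=0) * 100.0
        return cls(counts=counts, shares=shares, novel_tp_pct=novel_tp_pct)

    def write_tsv(self, path: str) -> None:
        joined = self.counts.join(self.shares, rsuffix="_pct").round(2)
        joined.to_csv(path, sep="\t", index_label="region_class")


def stratify_regions(
    callsets: Mapping[str, CallSet],
    novel: RegionSet,
    gold: Optional[CallSet] = None,
) -> StratificationReport:
    """Count each call set's sites inside and outside the novel regions.

    Shares are percentages of the class total across call sets (the
    comparison a novel-contig table makes).  When ``gold`` is given, TP
    percentages within the novel class are additionally reported per contig
    for each call set.
    """
    labels = list(callsets)
    counts = pd.DataFrame(0, index=["novel", "existing"], columns=labels, dtype=int)
    for label, cs in callsets.items():
        for s in cs.sites:
            cls = "novel" if novel.contains(s.contig, s.pos) else "existing"
            counts.loc[cls, label] += 1

    novel_tp = None
    if gold is not None:
        gold_novel = {k for k in gold.key_set() if novel.contains(k.contig, k.pos)}
        records: dict[str, dict[str, float]] = {}
        for label, cs in callsets.items():
            q_novel = {k for k in cs.key_set() if novel.contains(k.contig, k.pos)}
            for contig in sorted({k.contig for k in gold_novel}):
                g = {k for k in gold_novel if k.contig == contig}
                tp = len(g & q_novel)
                records.setdefault(contig, {})[label] = 100.0 * tp / len(g) if g else np.nan
        novel_tp = pd.DataFrame.from_dict(records, orient="index")
    return StratificationReport.from_counts(counts, novel_tp_pct=novel_tp)
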