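"""Annotation hard filtering and empirical cutoff derivation.

A :class:`FilterProfile` is a disjunction of threshold rules over site-level
annotations (or QUAL): a site failing any rule is soft-filtered with the
profile's fail label, never removed.  The built-in profiles transcribe the
production cutoffs used for the 1000 Genomes GRCh38 bcftools and Freebayes
call sets; :func:`derive_cutoffs` reconstructs such cutoffs from a
gold-standard comparison by taking a high quantile of the true-positive
annotation distribution on the rejecting side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Literal, Optional, Sequence

import numpy as np

from .model import CallSet, RegionSet, SiteKey, VariantSite

log = logging.getLogger(__name__)

__all__ = [
    "FilterRule",
    "FilterProfile",
    "LabeledSites",
    "builtin_profiles",
    "apply_profile",
    "label_against_gold",
    "derive_cutoffs",
]

Direction = Literal["reject_above", "reject_below"]


@dataclass(frozen=True)
class FilterRule:
    """Reject a site when an annotation crosses a threshold (strictly).

    ``annotation`` is an INFO key or the literal ``"QUAL"``.  Sites lacking
    the annotation follow ``missing_policy`` (default: pass).
    """

    annotation: str
    direction: Direction
    threshold: float
    missing_policy: Literal["pass", "fail"] = "pass"

    def __post_init__(self):
        if not self.annotation:
            raise ValueError("rule annotation must be non-empty")
        if not np.isfinite(self.threshold):
            raise ValueError("rule threshold must be finite")
        if self.direction not in ("reject_above", "reject_below"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def value_of(self, site: VariantSite) -> Optional[float]:
        if self.annotation == "QUAL":
            return site.qual
        v = site.info.get(self.annotation)
        return float(v) if isinstance(v, (int, float)) else None

    def rejects(self, site: VariantSite) -> Optional[bool]:
        """True/False when the annotation is present, None when missing."""
        v = self.value_of(site)
        if v is None:
            return None
        if self.direction == "reject_above":
            return v > self.threshold
        return v < self.threshold


@dataclass(frozen=True)
class FilterProfile:
    """A named OR-combination of rules plus the FILTER label applied on failure."""

    name: str
    rules: tuple[FilterRule, ...]
    fail_label: str

    def __post_init__(self):
        if not self.rules:
            raise ValueError("profile must carry at least one rule")

    @classmethod
    def from_dict(cls, d: dict) -> "FilterProfile":
        rules = tuple(
            FilterRule(
                annotation=r["annotation"],
                direction=r["direction"],
                threshold=float(r["threshold"]),
                missing_policy=r.get("missing_policy", "pass"),
            )
            for r in d["rules"]
        )
        return cls(name=d["name"], rules=rules, fail_label=d["fail_label"])

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "fail_label": self.fail_label,
            "rules": [
                {
                    "annotation": r.annotation,
                    "direction": r.direction,
                    "threshold": r.threshold,
                    "missing_policy": r.missing_policy,
                }
                for r in self.rules
            ],
        }

    @classmethod
    def from_json(cls, path: str) -> "FilterProfile":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


@dataclass
class LabeledSites:
    """TP/FP/FN site keys from a gold-standard comparison inside confidence regions."""

    tp_keys: set[SiteKey]
    fp_keys: set[SiteKey]
    fn_keys: set[SiteKey]

    def __post_init__(self):
        if self.tp_keys & self.fp_keys:
            raise ValueError("TP and FP key sets must be disjoint")


_PROFILE_FILES = ("lc_snv", "lc_indel", "ex_snv", "ex_indel", "freebayes")


def builtin_profiles() -> dict[str, FilterProfile]:
    """The shipped production filter profiles, loaded from package data.

    ``lc_*`` are the bcftools low-coverage WGS profiles, ``ex_*`` the
    bcftools whole-exome profiles (note: no depth rule for exome INDELs) and
    ``freebayes`` the single QUAL rule.  Thresholds are transcribed exactly.
    """
    out: dict[str, FilterProfile] = {}
    base = resources.files("consvar").joinpath("data/profiles")
    for name in _PROFILE_FILES:
        with base.joinpath(f"{name}.json").open() as fh:
            out[name] = FilterProfile.from_dict(json.load(fh))
    return out


def apply_profile(cs: CallSet, profile: FilterProfile) -> CallSet:
    """Soft-filter a call set: failing sites gain ``profile.fail_label``.

    No site is removed; passing sites keep their existing filter status.
    Counts of failed/passed sites and of missing-annotation rule evaluations
    are logged and stored under ``metadata['filter_summary']``.
    """
    sites: list[VariantSite] = []
    n_failed = 0
    n_missing = 0
    for site in cs.sites:
        rejected = False
        for rule in profile.rules:
            verdict = rule.rejects(site)
            if verdict is None:
                n_missing += 1
                verdict = rule.missing_policy == "fail"
            if verdict:
                rejected = True
                break
        if rejected:
            n_failed += 1
            sites.append(site.with_(filters=site.filters | {profile.fail_label}))
        else:
            sites.append(site)
    summary = {
        "profile": profile.name,
        "failed": n_failed,
        "passed": len(sites) - n_failed,
        "missing_annotation_evaluations": n_missing,
    }
    log.info("apply_profile %s", summary)
    out = cs.replace(sites=sites)
    out.metadata = dict(cs.metadata, filter_summary=summary)
    return out


def label_against_gold(query: CallSet, gold: CallSet, regions: RegionSet) -> LabeledSites:
    """Label query sites as TP/FP and gold-only sites as FN, within regions.

    Both call sets must be normalized and biallelic; matching is by
    :class:`~consvar.model.SiteKey`.  Sites outside the confidence regions
    are excluded from all three sets.
    """
    qkeys = {k for k in query.key_set() if regions.contains(k.contig, k.pos)}
    gkeys = {k for k in gold.key_set() if regions.contains(k.contig, k.pos)}
    return LabeledSites(tp_keys=qkeys & gkeys, fp_keys=qkeys - gkeys, fn_keys=gkeys - qkeys)


def derive_cutoffs(
    query: CallSet,
    labels: LabeledSites,
    annotations: Sequence[tuple[str, Direction]],
    tp_retention: float = 0.99,
    name: str = "derived",
    fail_label: str = "GIABFILTER",
) -> tuple[FilterProfile, dict[str, dict[str, float]]]:
    """Derive per-annotation cutoffs from the TP annotation distribution.

    For each ``(annotation, direction)`` pair the threshold is the empirical
    ``tp_retention``-quantile of the TP values on the rejecting side (upper
    quantile for reject-above, lower for reject-below), so at most
    ``(1 - tp_retention)`` of true positives would be rejected by that rule.
    Returns the assembled profile plus an audit table with the TP/FP counts
    each rule rejects on the labelled data.
    """
    if not 0.5 < tp_retention < 1:
        raise ValueError("tp_retention must lie in (0.5, 1)")
    by_key = {s.key(): s for s in query.sites}
    rules: list[FilterRule] = []
    audit: dict[str, dict[str, float]] = {}
    for annotation, direction in annotations:
        tp_vals = _values(by_key, labels.tp_keys, annotation)
        if tp_vals.size == 0:
            raise ValueError(f"annotation {annotation!r} absent on all TP sites")
        fp_vals = _values(by_key, labels.fp_keys, annotation)
        if direction == "reject_above":
            threshold = float(np.quantile(tp_vals, tp_retention, method="higher"))
        else:
            threshold = float(np.quantile(tp_vals, 1 - tp_retention, method="lower"))
        rule = FilterRule(annotation=annotation, direction=direction, threshold=threshold)
        rules.append(rule)
        reject = (lambda v: v > threshold) if direction == "reject_above" else (lambda v: v < threshold)
        audit[f"{annotation}:{direction}"] = {
            "threshold": threshold,
            "tp_rejected": int(np.sum([reject(v) for v in tp_vals])),
            "tp_total": int(tp_vals.size),
            "fp_rejected": int(np.sum([reject(v) for v in fp_vals])),
            "fp_total": int(fp_vals.size),
        }
    return FilterProfile(name=name, rules=tuple(rules), fail_label=fail_label), audit


def _values(by_key: dict, keys: Iterable[SiteKey], annotation: str) -> np.ndarray:
    vals = []
    for k in keys:
        site = by_key.get(k)
        if site is None:
            continue
        v = site.qual if annotation == "QUAL" else site.info.get(annotation)
        if isinstance(v, (int, float)):
            vals.append(float(v))
    return np.asarray(vals, dtype=float)
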