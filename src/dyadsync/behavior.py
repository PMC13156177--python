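"""Dyad-level behavioral indicators from per-second code streams, plus
coder-reliability statistics."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .types import UNSUPPORTIVE_ERSB, CodedStream


@dataclass
class SharedPositiveResult:
    prop: Optional[float]   # None when missing
    any_ind: Optional[int]
    missing: bool
    codable_frac_parent: float
    codable_frac_child: float


@dataclass
class UnsupportiveResult:
    prop: Optional[float]
    any_ind: Optional[int]
    missing: bool
    codable_frac: float


@dataclass
class BehaviorSummary:
    """Dyad-level behavioral indicators appended to the analysis table."""

    shared_positive_prop: Optional[float]
    shared_positive_any: Optional[int]
    unsupportive_prop: Optional[float]
    unsupportive_any: Optional[int]
    codable_frac_parent: Optional[float]
    codable_frac_child: Optional[float]


def shared_positive(
    parent: CodedStream,
    child: CodedStream,
    uncodable_max: float = 0.5,
) -> SharedPositiveResult:
    """Proportion of jointly codable seconds in which both members show
    positive/warm affect, and the any-shared-positive indicator.

    If the uncodable fraction of *either* stream exceeds ``uncodable_max``
    (strictly more than 50% by default), the dyad is missing on affect
    synchrony.
    """
    if parent.task_length_s != child.task_length_s:
        raise ValueError(
            f"stream length mismatch: parent {parent.task_length_s} vs "
            f"child {child.task_length_s}"
        )
    cf_p = parent.codable_frac
    cf_c = child.codable_frac
    if (1.0 - cf_p) > uncodable_max or (1.0 - cf_c) > uncodable_max:
        return SharedPositiveResult(None, None, True, cf_p, cf_c)

    both_codable = parent.codable_mask & child.codable_mask
    denom = int(np.sum(both_codable))
    if denom == 0:
        return SharedPositiveResult(None, None, True, cf_p, cf_c)
    shared = np.sum(
        both_codable
        & (parent.codes == "positive_warm")
        & (child.codes == "positive_warm")
    )
    prop = float(shared) / denom
    return SharedPositiveResult(prop, int(prop > 0), False, cf_p, cf_c)


def unsupportive_indicator(ersb: CodedStream) -> UnsupportiveResult:
    """Proportion of codable seconds spent in unsupportive ERSB (dismissing,
    mild rejection, firm rejection) and its any-use dichotomization."""
    if ersb.stream_kind != "ersb":
        raise ValueError(f"expected an ersb stream, got {ersb.stream_kind!r}")
    codable = ersb.codable_mask
    denom = int(np.sum(codable))
    if denom == 0:
        return UnsupportiveResult(None, None, True, ersb.codable_frac)
    unsupportive = np.isin(ersb.codes, UNSUPPORTIVE_ERSB) & codable
    prop = float(np.sum(unsupportive)) / denom
    return UnsupportiveResult(prop, int(prop > 0), False, ersb.codable_frac)


def timeunit_kappa(coder_a: CodedStream, coder_b: CodedStream) -> float:
    """Cohen's kappa over per-second epochs, excluding seconds either coder
    marked uncodable. Returns NaN (with a warning) when chance agreement is 1.
    """
    if coder_a.stream_kind != coder_b.stream_kind:
        raise ValueError("coders must use the same alphabet")
    if coder_a.task_length_s != coder_b.task_length_s:
        raise ValueError(
            f"stream length mismatch: {coder_a.task_length_s} vs {coder_b.task_length_s}"
        )
    keep = coder_a.codable_mask & coder_b.codable_mask
    a = coder_a.codes[keep]
    b = coder_b.codes[keep]
    n = len(a)
    if n == 0:
        warnings.warn("no jointly codable seconds; kappa undefined")
        return float("nan")
    cats = sorted(set(a) | set(b))
    index = {c: i for i, c in enumerate(cats)}
    confusion = np.zeros((len(cats), len(cats)))
    for x, y in zip(a, b):
        confusion[index[x], index[y]] += 1
    p_o = np.trace(confusion) / n
    p_e = float(np.sum(confusion.sum(axis=1) * confusion.sum(axis=0))) / n**2
    if p_e >= 1.0 - 1e-15:
        warnings.warn("single shared category; kappa undefined (p_e = 1)")
        return float("nan")
    return float((p_o - p_e) / (1.0 - p_e))


def behavior_summary(
    parent_affect: Optional[CodedStream],
    child_affect: Optional[CodedStream],
    parent_ersb: Optional[CodedStream],
    uncodable_max: float = 0.5,
) -> BehaviorSummary:
    """Combine the affect-synchrony and ERSB indicators for one dyad,
    propagating missing components."""
    sp = (
        shared_positive(parent_affect, child_affect, uncodable_max)
        if parent_affect is not None and child_affect is not None
        else None
    )
    un = unsupportive_indicator(parent_ersb) if parent_ersb is not None else None
    return BehaviorSummary(
        shared_positive_prop=sp.prop if sp else None,
        shared_positive_any=sp.any_ind if sp else None,
        unsupportive_prop=un.prop if un else None,
        unsupportive_any=un.any_ind if un else None,
        codable_frac_parent=sp.codable_frac_parent if sp else (
            parent_affect.codable_frac if parent_affect is not None else None
        ),
        codable_frac_child=sp.codable_frac_child if sp else (
            child_affect.codable_frac if child_affect is not None else None
        ),
    )
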