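"""All-or-none classification of SNPs across replicated selection lines.

A SNP is *all-or-none* when every replicate line of one line type is fixed for
the same allele while every replicate line of the other type is not fixed for
that allele (or vice versa).  Two readings of "not fixed" are supported:

``not_fixed_for_focal``
    a line of the other type fails the criterion as soon as its frequency of
    the group-fixed allele is below 1 (minus the tolerance); a line fixed for
    the *opposite* allele still counts as "not fixed" for the group allele.
``strict_polymorphic``
    a line of the other type must be strictly segregating (frequency strictly
    between the fixation tolerances) to fail the criterion.

The default is ``not_fixed_for_focal``, the literal reading of the pattern
definition; the stricter reading is exposed for sensitivity analyses.
"""

from __future__ import annotations

from collections import Counter

from .model import (
    ClassifiedSnp,
    LineDesign,
    ParameterError,
    SnpPanel,
    SnpRecord,
    ValidationError,
)

MODES = ("not_fixed_for_focal", "strict_polymorphic")

FIXED_FOCAL = "fixed_focal"
FIXED_OTHER = "fixed_other"
SEGREGATING = "segregating"


def _check_delta(delta: float, name: str = "delta") -> None:
    if not 0.0 <= delta < 0.5:
        raise ParameterError(f"{name} must be in [0, 0.5), got {delta}")


def is_fixed(freq: float, delta: float = 0.0) -> str:
    """Fixation state of a focal-allele frequency.

    Returns ``"fixed_focal"`` iff ``freq >= 1 - delta``, ``"fixed_other"`` iff
    ``freq <= delta``, else ``"segregating"``.  ``delta`` (default 0: exact
    fixation) absorbs sampling noise in empirical frequency estimates.
    """
    _check_delta(delta)
    if not 0.0 <= freq <= 1.0:
        raise ValidationError(f"frequency {freq} outside [0, 1]")
    if freq >= 1.0 - delta:
        return FIXED_FOCAL
    if freq <= delta:
        return FIXED_OTHER
    return SEGREGATING


def _fails_fixation(freq_of_fixed: float, mode: str, fail_delta: float) -> bool:
    """Does a line of the opposite type fail the fixation criterion?

    ``freq_of_fixed`` is the line's frequency of the allele the candidate
    group is fixed for.
    """
    if mode == "not_fixed_for_focal":
        return freq_of_fixed < 1.0 - fail_delta
    # strict_polymorphic: the line itself must be segregating
    return fail_delta < freq_of_fixed < 1.0 - fail_delta


def classify_all_or_none(
    snp: SnpRecord,
    design: LineDesign,
    mode: str = "not_fixed_for_focal",
    delta: float = 0.0,
    fail_delta: float | None = None,
) -> ClassifiedSnp:
    """Classify one SNP against the replicate-line design.

    ``delta`` is the fixation tolerance; ``fail_delta`` (defaults to
    ``delta``) is the tolerance used on the non-fixed side, separable so the
    fixation criterion can be relaxed without weakening the failure criterion.
    """
    if mode not in MODES:
        raise ParameterError(f"unknown mode {mode!r}; expected one of {MODES}")
    _check_delta(delta)
    if fail_delta is None:
        fail_delta = delta
    _check_delta(fail_delta, "fail_delta")
    missing = [lid for lid in design.line_ids if lid not in snp.freqs]
    if missing:
        raise ValidationError(f"{snp.snp_id}: missing frequency for line(s) {missing}")

    for fixed_type, other_type in (("selected", "control"), ("control", "selected")):
        fixed_freqs = [snp.freqs[lid] for lid in design.ids_of(fixed_type)]
        states = {is_fixed(f, delta) for f in fixed_freqs}
        if len(states) != 1 or states == {SEGREGATING}:
            continue
        allele = "focal" if states == {FIXED_FOCAL} else "other"
        other_freqs = [snp.freqs[lid] for lid in design.ids_of(other_type)]
        if allele == "other":
            other_freqs = [1.0 - f for f in other_freqs]
        if all(_fails_fixation(f, mode, fail_delta) for f in other_freqs):
            return ClassifiedSnp(
                snp=snp,
                is_all_or_none=True,
                fixed_linetype=fixed_type,
                fixed_allele=allele,
            )
    return ClassifiedSnp(snp=snp, is_all_or_none=False)


def classify_panel(
    panel: SnpPanel,
    mode: str = "not_fixed_for_focal",
    delta: float = 0.0,
    fail_delta: float | None = None,
) -> tuple[list[ClassifiedSnp], dict]:
    """Classify every record of a panel, preserving input (coordinate) order.

    Returns the per-SNP classifications and a summary dict with the total
    count, the all-or-none count, and counts broken down by
    (fixed_linetype, fixed_allele).
    """
    classified = [
        classify_all_or_none(rec, panel.design, mode=mode, delta=delta, fail_delta=fail_delta)
        for rec in panel.records
    ]
    by_direction = Counter(
        (c.fixed_linetype, c.fixed_allele) for c in classified if c.is_all_or_none
    )
    summary = {
        "n_snps": len(classified),
        "n_all_or_none": sum(c.is_all_or_none for c in classified),
        "by_direction": dict(by_direction),
        "mode": mode,
        "delta": delta,
    }
    return classified, summary


def all_or_none_ids(classified: list[ClassifiedSnp]) -> list[str]:
    """Snp ids of the all-or-none subset, in input order."""
    return [c.snp.snp_id for c in classified if c.is_all_or_none]
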