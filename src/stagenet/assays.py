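"""Wet-lab quantification formulas as pure utility calculations."""

from __future__ import annotations

import warnings


def wound_healing_rate(area_0: float, area_t: float) -> float:
    """Percent scratch closure: ``(1 - area_t / area_0) * 100``.

    Unit-free (any consistent area unit).  A widened wound (area_t > area_0)
    yields a negative rate with a warning rather than an error.
    """
    if area_0 <= 0:
        raise ValueError("initial scratch area must be positive")
    if area_t < 0:
        raise ValueError("scratch area cannot be negative")
    rate = (1.0 - area_t / area_0) * 100.0
    if rate < 0:
        warnings.warn("scratch area grew over time; negative healing rate")
    return rate


def ddct_fold_change(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference gene) within each condition; the fold
    change of case over control is ``2 ** -(dCt_case - dCt_ctrl)``.  This is
    the standard reading of Ct-based relative quantification against a
    housekeeping reference such as GAPDH; amplification-efficiency
    correction is out of scope.
    """
    for v in (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl):
        if not (v == v and abs(v) != float("inf")):
            raise ValueError("Ct values must be finite")
    dct_case = ct_target_case - ct_ref_case
    dct_ctrl = ct_target_ctrl - ct_ref_ctrl
    return 2.0 ** -(dct_case - dct_ctrl)
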