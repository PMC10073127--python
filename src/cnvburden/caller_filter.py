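"""Call-level quality filtering.

Only CNVnator calls carry quality fields and therefore call-level filters;
the other callers' output is used as produced (default parameters) and is
passed through unchanged.

A CNVnator call is retained iff all of:

1. ``eval1 < max_eval`` and ``eval2 < max_eval`` (default ceiling 1e-3);
2. ``q0 < max_q0`` and ``q0 != -1`` (default ceiling 0.5; -1 is the
   undefined sentinel and always fails);
3. for deletion calls only, ``norm_rd < del_rd_factor * (1 + q0)``
   (default factor 0.75) — a depth consistency check: a real loss should
   show depleted normalised read depth even after allowing for the
   zero-quality-read fraction.  Duplication calls are exempt.

All inequalities are strict; boundary values (eval exactly ``max_eval``,
q0 exactly ``max_q0``) are removed.  ``eval3``/``eval4`` are carried but
not consulted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable

from .errors import ValidationError
from .io_formats import KNOWN_CALLERS, CnvCall, EventType


@dataclass(frozen=True)
class CnvnatorFilterParams:
    """Thresholds for the three CNVnator call filters."""

    max_eval: float = 1.0e-3
    max_q0: float = 0.5
    del_rd_factor: float = 0.75

    def __post_init__(self) -> None:
        if self.max_eval <= 0 or self.max_q0 <= 0 or self.del_rd_factor <= 0:
            raise ValidationError("filter thresholds must all be positive")
        if self.max_q0 > 1:
            raise ValidationError(f"max_q0 must be <= 1, got {self.max_q0}")


def _check_fields(call: CnvCall) -> None:
    for name in ("eval1", "eval2", "q0", "norm_rd"):
        if getattr(call, name) is None:
            raise ValidationError(
                f"cnvnator call {call.sample_id} {call.interval} "
                f"has null required field {name!r}"
            )


def cnvnator_call_passes(call: CnvCall, params: CnvnatorFilterParams) -> bool:
    """Apply the three retention rules to one CNVnator call."""
    _check_fields(call)
    if not (call.eval1 < params.max_eval and call.eval2 < params.max_eval):
        return False
    if call.q0 == -1 or not (call.q0 < params.max_q0):
        return False
    if call.event_type is EventType.DEL:
        if not (call.norm_rd < params.del_rd_factor * (1.0 + call.q0)):
            return False
    return True


def filter_cnvnator_calls(
    calls: Iterable[CnvCall],
    params: CnvnatorFilterParams = CnvnatorFilterParams(),
) -> list[CnvCall]:
    """Retain CNVnator calls passing all three rules, order preserved."""
    return [c for c in calls if cnvnator_call_passes(c, params)]


def filter_calls(
    calls: Iterable[CnvCall],
    params: CnvnatorFilterParams = CnvnatorFilterParams(),
    known_callers: tuple[str, ...] = KNOWN_CALLERS,
) -> list[CnvCall]:
    """Route a mixed-caller list through the appropriate filter.

    CNVnator calls go through :func:`filter_cnvnator_calls`; every other
    known caller's calls are returned unchanged.  An unknown ``caller_id``
    triggers a warning and passes through.  Output order is preserved.
    """
    warned: set[str] = set()
    out: list[CnvCall] = []
    for c in calls:
        if c.caller_id == "cnvnator":
            if cnvnator_call_passes(c, params):
                out.append(c)
        else:
            if c.caller_id not in known_callers and c.caller_id not in warned:
                warnings.warn(
                    f"unknown caller_id {c.caller_id!r}: passing calls through "
                    "unfiltered",
                    stacklevel=2,
                )
                warned.add(c.caller_id)
            out.append(c)
    return out
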