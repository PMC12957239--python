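"""Binary triage labels and their mapping rules.

Two labeling schemes coexist in intrapartum CTG work:

* ``figo_binary`` — expert FIGO categories, with Category I (Normal) mapped
  to *Reassuring* and Categories II (Suspicious) and III (Abnormal)
  amalgamated into *Non-Reassuring*;
* ``ph_threshold`` — the objective umbilical-artery pH outcome, with
  pH >= 7.05 *Reassuring* and pH < 7.05 *Non-Reassuring* (the boundary value
  7.05 itself is reassuring).
"""

from __future__ import annotations

from dataclasses import dataclass

from .chart_synthesis import NON_REASSURING, REASSURING

FIGO_NORMAL = "normal"
FIGO_SUSPICIOUS = "suspicious"
FIGO_ABNORMAL = "abnormal"

PH_THRESHOLD = 7.05


def map_label(figo: str | None = None, ph: float | None = None,
              scheme: str = "figo_binary") -> str:
    """Map a FIGO category or a pH value to the binary triage label."""
    if scheme == "figo_binary":
        if figo is None:
            raise ValueError("figo_binary scheme requires a FIGO category")
        if figo == FIGO_NORMAL:
            return REASSURING
        if figo in (FIGO_SUSPICIOUS, FIGO_ABNORMAL):
            return NON_REASSURING
        raise ValueError(f"unknown FIGO category {figo!r}")
    if scheme == "ph_threshold":
        if ph is None:
            raise ValueError("ph_threshold scheme requires a pH value")
        return REASSURING if ph >= PH_THRESHOLD else NON_REASSURING
    raise ValueError(f"unknown labeling scheme {scheme!r}")


@dataclass
class RecordLabel:
    """A record's label provenance: FIGO category and/or pH, plus the
    derived binary label."""

    record_id: str
    binary: str
    figo: str | None = None
    ph: float | None = None

    def __post_init__(self) -> None:
        if self.binary not in (REASSURING, NON_REASSURING):
            raise ValueError(f"unknown binary label {self.binary!r}")
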