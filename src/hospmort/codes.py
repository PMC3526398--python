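"""Referral diagnosis code sets per condition.

The admission conditions are identified upstream (the ``condition`` column is
taken as given); these code sets are used only to decide whether a cause of
death "matches" the referral diagnosis, by prefix comparison so that subcodes
(e.g. ``820.2`` under ``820``, ``I21.1`` under ``I21``) match their stem.
"""

from __future__ import annotations

CONDITIONS = ("AMI", "stroke", "hip_fracture")

# ICD-9 and ICD-10 stems per referral condition.
REFERRAL_CODES: dict[str, tuple[str, ...]] = {
    "AMI": ("410", "I21.0", "I21.1", "I21.2", "I21.3"),
    "stroke": ("431", "434", "436", "I61", "I63", "I64"),
    "hip_fracture": ("820", "S72.0", "S72.1", "S72.2"),
}

# Pool of plausible non-matching causes used by the simulator.
NON_MATCHING_CODES: tuple[str, ...] = (
    "J18.9",  # pneumonia
    "C80.9",  # malignant neoplasm, unspecified
    "N17.9",  # acute kidney failure
    "E11.9",  # type 2 diabetes
    "G30.9",  # Alzheimer disease
    "I50.9",  # heart failure
)


def code_matches(code: str, condition: str) -> bool:
    """True if ``code`` falls under any referral stem for ``condition``."""
    if not code:
        return False
    stems = REFERRAL_CODES[condition]
    code = code.strip()
    return any(code == s or code.startswith(s) for s in stems)


def cause_of_death_matches(
    underlying: str | None, contributing: list[str] | tuple[str, ...], condition: str
) -> bool:
    """True if the underlying or any contributing cause matches the referral codes."""
    if underlying and code_matches(underlying, condition):
        return True
    return any(code_matches(c, condition) for c in contributing if c)
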