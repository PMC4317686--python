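"""Bidirectional Sanger concordance verification.

Each variant that survives the initial triage is re-sequenced by capillary
(Sanger) sequencing in the affected NGS carriers, on both strands. The
decision rule classifies each interrogated variant:

* ``FULLY_VERIFIED`` — every expected affected carrier has forward and
  reverse reads concordant with the NGS call;
* ``PARTIALLY_VALIDATED`` — at least one individual has both strands
  concordant, but not all expected carriers do;
* ``DESIGN_FAILED`` — no individual has both strands concordant (covers
  assays with no usable reads at all, e.g. failed primer design in
  repetitive regions, and assays whose reads disagree with NGS).

Quality-failed reads are expected to be encoded upstream as no-read (N).
Unaffected relatives' Sanger reads are descriptive only and never affect
the status.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .model import VariantKey
else:
    VariantKey = tuple


class StrandCall(enum.Enum):
    """Agreement of one Sanger strand read with the NGS call."""

    CONCORDANT = "C"
    DISCORDANT = "D"
    NO_READ = "N"


class VerificationStatus(enum.Enum):
    FULLY_VERIFIED = "fully_verified"
    PARTIALLY_VALIDATED = "partially_validated"
    DESIGN_FAILED = "design_failed"

    @property
    def at_least_partial(self) -> bool:
        return self is not VerificationStatus.DESIGN_FAILED


@dataclass(frozen=True)
class SangerObservation:
    """Forward/reverse strand calls for one individual at one variant."""

    variant_key: "VariantKey"
    individual_id: str
    forward_call: StrandCall
    reverse_call: StrandCall

    @property
    def both_concordant(self) -> bool:
        return (
            self.forward_call is StrandCall.CONCORDANT
            and self.reverse_call is StrandCall.CONCORDANT
        )

    @property
    def has_read(self) -> bool:
        return (
            self.forward_call is not StrandCall.NO_READ
            or self.reverse_call is not StrandCall.NO_READ
        )


def verify_variant(
    observations: Sequence[SangerObservation],
    expected_carriers: Iterable[str] | None = None,
) -> VerificationStatus:
    """Classify one variant from its per-individual strand observations.

    Parameters
    ----------
    observations
        All Sanger observations for this variant (affected carriers).
    expected_carriers
        Individual ids of the affected NGS carriers the assay was meant to
        confirm. Defaults to the observed individuals; if given, every
        observed individual must be among them, and full verification
        requires both strands concordant in *every* expected carrier.
    """
    observed = {o.individual_id for o in observations}
    if expected_carriers is None:
        expected = observed
    else:
        expected = set(expected_carriers)
        stray = observed - expected
        if stray:
            raise ValueError(
                f"Sanger observations for individuals who are not expected "
                f"carriers: {sorted(stray)}"
            )

    confirmed = {o.individual_id for o in observations if o.both_concordant}
    if expected and confirmed == expected:
        return VerificationStatus.FULLY_VERIFIED
    if confirmed:
        return VerificationStatus.PARTIALLY_VALIDATED
    return VerificationStatus.DESIGN_FAILED


def verification_summary(
    statuses: Mapping["VariantKey", VerificationStatus] | Iterable[VerificationStatus],
) -> Counter:
    """Count interrogated variants per verification status."""
    if isinstance(statuses, Mapping):
        statuses = statuses.values()
    counts: Counter = Counter({s: 0 for s in VerificationStatus})
    counts.update(statuses)
    return counts
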