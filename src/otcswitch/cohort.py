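"""Population cascade: derive the six treatment-status segments.

Starting from a country's total population, the cascade applies the adult
fraction and migraine prevalence, then splits by diagnosis, treatment and
prescription status into six segments:

* Pop 1 — diagnosed, on the Rx triptan to be switched
* Pop 2 — diagnosed, on other Rx triptans
* Pop 3 — diagnosed, self-treating with OTC products
* Pop 4 — diagnosed, untreated
* Pop 5 — undiagnosed, self-treating with OTC products
* Pop 6 — undiagnosed, untreated

Patients prescribed non-triptan Rx drugs (the remainder of the Rx-treated
group after Pop 1 and Pop 2) are excluded from all cost flows.  Segment sizes
are kept fractional internally; rounding to whole persons happens only at
display time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .parameters import CountryEpidemiology

__all__ = ["PopulationSegments", "derive_segments", "segments_from_counts"]


@dataclass(frozen=True)
class PopulationSegments:
    """Sizes (persons, possibly fractional) of the cascade levels and Pop 1-6."""

    adults_with_migraine: float
    diagnosed: float
    treated: float
    rx_treated: float
    pop1: float
    pop2: float
    pop3: float
    pop4: float
    pop5: float
    pop6: float

    @property
    def rx_triptan(self) -> float:
        """Patients on any Rx triptan (Pop 1 + Pop 2)."""
        return self.pop1 + self.pop2

    @property
    def otc_or_untreated(self) -> float:
        """Patients not on Rx triptans (Pop 3 + Pop 4 + Pop 5 + Pop 6)."""
        return self.pop3 + self.pop4 + self.pop5 + self.pop6

    def pop(self, segment: int) -> float:
        if not 1 <= segment <= 6:
            raise ValueError(f"segment must be 1..6, got {segment}")
        return getattr(self, f"pop{segment}")


def derive_segments(epi: CountryEpidemiology) -> PopulationSegments:
    """Apply the cascade rates; explicit overrides replace derived segments.

    Overrides exist because published Pop 1/Pop 2 counts were calibrated with
    sales data and cannot be reproduced exactly from the rounded cascade
    percentages.
    """
    adults = (
        epi.population_size * epi.fraction_over_18 * epi.migraine_prevalence
    )
    diagnosed = adults * epi.diagnosis_rate
    treated = diagnosed * epi.treated_fraction
    rx_treated = treated * epi.rx_treated_fraction
    undiagnosed = adults - diagnosed
    pop1 = rx_treated * epi.triptan_fraction * epi.switched_triptan_fraction
    pop2 = rx_treated * epi.triptan_fraction - pop1
    pop5 = undiagnosed * epi.undiagnosed_treated_fraction
    seg = PopulationSegments(
        adults_with_migraine=adults,
        diagnosed=diagnosed,
        treated=treated,
        rx_treated=rx_treated,
        pop1=pop1,
        pop2=pop2,
        pop3=treated - rx_treated,
        pop4=diagnosed - treated,
        pop5=pop5,
        pop6=undiagnosed - pop5,
    )
    if epi.segment_overrides is not None:
        seg = replace(seg, **epi.segment_overrides.as_dict())
    return seg


def segments_from_counts(
    pop1: float = 0.0,
    pop2: float = 0.0,
    pop3: float = 0.0,
    pop4: float = 0.0,
    pop5: float = 0.0,
    pop6: float = 0.0,
) -> PopulationSegments:
    """Build segments directly from counts (toy cohorts, oracle tests).

    Cascade aggregates are reconstructed consistently: the Rx-triptan
    segments are taken as the whole Rx-treated group.
    """
    if min(pop1, pop2, pop3, pop4, pop5, pop6) < 0:
        raise ValueError("segment counts must be non-negative")
    rx_treated = pop1 + pop2
    treated = rx_treated + pop3
    diagnosed = treated + pop4
    return PopulationSegments(
        adults_with_migraine=diagnosed + pop5 + pop6,
        diagnosed=diagnosed,
        treated=treated,
        rx_treated=rx_treated,
        pop1=pop1,
        pop2=pop2,
        pop3=pop3,
        pop4=pop4,
        pop5=pop5,
        pop6=pop6,
    )
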