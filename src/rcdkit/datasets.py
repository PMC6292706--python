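"""Published summary data shipped with the package.

The mating-trial outcome table for the *Littoraria cingulata* / *L. filosa*
sister-species pair: counts of no-choice trials in which at least one
mounting was observed within the 2-h observation window, out of the number
of trials conducted, per female species x male species cell and location
class.  Cell order is (female, male) over ("cingulata", "filosa").
"""

from __future__ import annotations

from .mating import MatingCountTable

# (female, male) cell order: CC, CF, FC, FF
_MOUNTING_COUNTS = {
    "sympatric": ([54, 4, 28, 33], [117, 115, 117, 119]),
    "allopatric": ([38, 40, 49, 86], [118, 117, 118, 119]),
}


def mating_trial_table(location_class: str) -> MatingCountTable:
    """The published mating-trial outcome table for one location class."""
    try:
        counts, totals = _MOUNTING_COUNTS[location_class]
    except KeyError:
        raise ValueError(f"unknown location class {location_class!r}") from None
    return MatingCountTable(counts, totals, location_class)
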