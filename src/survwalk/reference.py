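"""Published characteristics of the glioma discovery cohort.

The 160-sample cohort behind the original module was randomly halved into a
training and a testing set; these constants record the printed per-set WHO
grade composition and survival status, and are used for consistency
arithmetic (grade strata must sum to the set sizes; the high-grade testing
subgroup is the grade III + IV testing samples).
"""

from __future__ import annotations

#: WHO grade composition per sample set
GRADE_COUNTS: dict[str, dict[str, int]] = {
    "training": {"II": 32, "III": 16, "IV": 32},
    "testing": {"II": 31, "III": 17, "IV": 32},
    "entire": {"II": 63, "III": 33, "IV": 64},
}

#: declared sample-set sizes
SET_SIZES: dict[str, int] = {"training": 80, "testing": 80, "entire": 160}

#: vital status per sample set (alive = censored, deceased = event)
SURVIVAL_STATUS: dict[str, dict[str, int]] = {
    "training": {"alive": 41, "deceased": 39},
    "testing": {"alive": 51, "deceased": 29},
    "entire": {"alive": 92, "deceased": 68},
}

#: declared size of the high-grade (III + IV) testing subgroup
HIGH_GRADE_TESTING_N = 49


def grade_total(which: str) -> int:
    """Sum of the per-grade counts of one sample set."""
    return sum(GRADE_COUNTS[which].values())


def high_grade_count(which: str) -> int:
    """Grade III + IV sample count of one sample set."""
    counts = GRADE_COUNTS[which]
    return counts["III"] + counts["IV"]
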