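"""Ready-made cohort specifications.

:func:`mandalay_survey_spec` encodes the published carrier counts of a
2019 five-township *Ae. aegypti* survey of the Mandalay area (Myanmar)
as a synthetic cohort: 394 paired-amplicon individuals split
139/130/83/30/12 across Naung Cho, Chan Aye Thazan, Patheingyi,
Aung Myae Tharsan and Pyin Oo Lwin, carrying S989P in 216, V1016G in
290, F1534C in 274, T1520I in 2, F1534L in 2 (both from Patheingyi),
F1020S in 50 and E1553G in 10 individuals.  Per-township S989P counts
follow the published township frequencies; the remaining singles are
allocated so that every township's V1016G and F1534C frequency stays in
the published 50-93% band.

With ``include_failures=True`` the cohort additionally contains the 17
individuals whose PCR failed (5 losing both regions, 12 losing one), for
a collected total of 411 -- these individuals are wild type, since no
sequence was ever obtained from them.

:func:`haplotype_panel_spec` is a minimal cohort with exactly one
individual per recurrent haplotype H1-H11, used to exercise the
labelling scheme end to end.
"""

from __future__ import annotations

from kdrseq.cohort import CohortSpec, Dropout, IndividualGroup, PopulationSpec
from kdrseq.haplotypes import STANDARD_NAMES, WILD_ALLELES

# recurrent combination haplotypes, by survey label
_H = {label: alleles for alleles, label in STANDARD_NAMES.items()}

F1020S = (1020, "S")
E1553G = (1553, "G")

#: (township, groups); each group: (haplotype label, extras, count)
_SURVEY_PLAN: tuple[tuple[str, tuple[tuple[str, tuple, int], ...]], ...] = (
    (
        "Naung Cho",
        (
            ("H9", (F1020S,), 22),
            ("H9", (), 32),
            ("H4+T1520I", (), 1),
            ("H4", (), 20),
            ("H3", (), 43),
            ("H1", (), 21),
        ),
    ),
    (
        "Chan Aye Thazan",
        (
            ("H9", (F1020S,), 20),
            ("H9", (E1553G,), 9),
            ("H9", (), 38),
            ("H4+T1520I", (), 1),
            ("H4", (), 20),
            ("H3", (), 23),
            ("H1", (), 19),
        ),
    ),
    (
        "Patheingyi",
        (
            ("H10", (), 2),
            ("H9", (F1020S,), 4),
            ("H9", (), 60),
            ("H4", (), 10),
            ("H3", (), 7),
        ),
    ),
    (
        "Aung Myae Tharsan",
        (
            ("H9", (F1020S,), 2),
            ("H9", (E1553G,), 1),
            ("H9", (), 18),
            ("H4", (), 5),
            ("H1", (), 4),
        ),
    ),
    (
        "Pyin Oo Lwin",
        (
            ("H9", (F1020S,), 2),
            ("H9", (), 6),
            ("H4", (), 3),
            ("H3", (), 1),
        ),
    ),
)

#: extra collected-but-failed individuals per township (sums to 17)
_FAILED_BY_TOWNSHIP = {
    "Naung Cho": 6,
    "Chan Aye Thazan": 6,
    "Patheingyi": 3,
    "Aung Myae Tharsan": 1,
    "Pyin Oo Lwin": 1,
}


def _resolve(label: str) -> tuple[str, str, str, str]:
    if label == "H4+T1520I":
        # F1534C carrier that additionally carries T1520I (counted once
        # for each mutation; the combination equals haplotype H8)
        return _H["H8"]
    return _H[label]


def mandalay_survey_spec(
    include_failures: bool = False,
    clones_per_individual: int = 3,
    noise_rate: float = 0.0,
    seed: int = 0,
) -> CohortSpec:
    """Cohort spec reproducing the survey's published carrier counts."""
    populations = []
    for name, groups in _SURVEY_PLAN:
        gs = [
            IndividualGroup(
                haplotype=_resolve(label),
                extra_mutations=extras,
                count=count,
            )
            for label, extras, count in groups
            if count > 0
        ]
        if include_failures and _FAILED_BY_TOWNSHIP.get(name):
            gs.append(
                IndividualGroup(
                    haplotype=WILD_ALLELES,
                    extra_mutations=(),
                    count=_FAILED_BY_TOWNSHIP[name],
                )
            )
        populations.append(PopulationSpec(name=name, groups=tuple(gs)))
    dropout = Dropout(both_fail=5, one_fail=12) if include_failures else Dropout()
    return CohortSpec(
        populations=tuple(populations),
        clones_per_individual=clones_per_individual,
        noise_rate=noise_rate,
        dropout=dropout,
        seed=seed,
    )


def haplotype_panel_spec(
    clones_per_individual: int = 2, seed: int = 0
) -> CohortSpec:
    """One individual per recurrent haplotype H1-H11, in label order."""
    groups = tuple(
        IndividualGroup(haplotype=_H[f"H{i}"], count=1) for i in range(1, 12)
    )
    return CohortSpec(
        populations=(PopulationSpec(name="panel", groups=groups),),
        clones_per_individual=clones_per_individual,
        seed=seed,
    )
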