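"""Published interaction estimates from the HRS smoking gene–environment study.

The original analysis crossed a dichotomized smoking polygenic score
(top quartile = high genetic risk, G) with five adverse early
psychosocial factors (E) among European-American (EA) and
African-American (AA) Health and Retirement Study participants, and
reported, per group × factor block: the four G×E cell counts, the three
single-model odds ratios (G only, E only, joint) against the doubly
unexposed reference, stratified ORs, the multiplicative-scale ratio and
the additive-scale RERI, each with 95% CIs.

The individual-level data behind these estimates are access-restricted,
so the printed numbers are kept here verbatim as inputs: they seed the
exact-count cohort mode, anchor worked-example tests, and feed the
internal-arithmetic checks (RERI = OR11 − OR10 − OR01 + 1, multiplicative
ratio = OR11 / (OR10·OR01), stratum OR identities).

Two published blocks are known to be irregular and are stored as printed:
the EA financial-burden row pairs the larger cell with the G=1 label, and
the AA father-education ORs/CIs are not mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .cohort import CellCounts

#: (estimate, ci_low, ci_high)
Est = tuple[float, float, float]
#: (estimate, ci_low, ci_high, p)
EstP = tuple[float, float, float, float]


@dataclass(frozen=True)
class PublishedBlock:
    """One published group × EPF interaction block."""

    group: str
    epf: str
    n: int
    cells: CellCounts
    or10: Est  #: genetic exposure only (G=1, E=0) vs doubly unexposed
    or01: Est  #: adverse EPF only (G=0, E=1) vs doubly unexposed
    or11: Est  #: jointly exposed vs doubly unexposed
    stratum_g_in_e1: Est  #: OR of G within the adverse-EPF stratum
    stratum_e_in_g1: Est  #: OR of the EPF within the high-genetic-risk stratum
    multiplicative: EstP
    reri: EstP


def _block(group, epf, n, cells, or10, or01, or11, sg, se, mult, reri):
    return PublishedBlock(
        group=group,
        epf=epf,
        n=n,
        cells=CellCounts(
            {
                (0, 0): cells[0],
                (1, 0): cells[1],
                (0, 1): cells[2],
                (1, 1): cells[3],
            }
        ),
        or10=or10,
        or01=or01,
        or11=or11,
        stratum_g_in_e1=sg,
        stratum_e_in_g1=se,
        multiplicative=mult,
        reri=reri,
    )


# Cell order: (G=0,E=0), (G=1,E=0), (G=0,E=1), (G=1,E=1); each (cases, total).
PUBLISHED: Mapping[str, Mapping[str, PublishedBlock]] = {
    "EA": {
        "maternal_warmth": _block(
            "EA", "maternal_warmth", 5572,
            [(1574, 3063), (547, 1004), (629, 1120), (248, 385)],
            (1.10, 0.95, 1.28), (1.21, 1.05, 1.39), (1.73, 1.37, 2.17),
            (1.43, 1.11, 1.83), (1.57, 1.22, 2.01),
            (1.3, 0.98, 1.72, 0.07), (0.42, 0.0, 0.84, 0.03),
        ),
        "financial_burden": _block(
            "EA", "financial_burden", 6868,
            [(905, 1549), (2517, 4717), (111, 168), (247, 434)],
            (1.23, 1.08, 1.39), (1.14, 0.93, 1.40), (1.75, 1.25, 2.44),
            (1.53, 1.05, 2.23), (1.45, 1.01, 2.00),
            (1.25, 0.84, 1.85, 0.28), (0.39, -0.24, 1.03, 0.11),
        ),
        "childhood_stress": _block(
            "EA", "childhood_stress", 6187,
            [(632, 1138), (1719, 3488), (275, 410), (731, 1151)],
            (1.27, 1.1, 1.47), (1.71, 1.48, 1.97), (2.02, 1.61, 2.52),
            (1.18, 0.92, 1.51), (1.58, 1.24, 2.02),
            (0.93, 0.7, 1.22, 0.58), (0.04, -0.47, 0.53, 0.44),
        ),
        "father_education": _block(
            "EA", "father_education", 6151,
            [(2002, 3831), (753, 1275), (408, 780), (148, 265)],
            (1.32, 1.15, 1.51), (1.09, 0.92, 1.28), (1.24, 0.95, 1.61),
            (1.14, 0.85, 1.52), (0.94, 0.71, 1.24),
            (0.86, 0.63, 1.18, 0.36), (-0.17, -0.55, 0.21, 0.81),
        ),
        "mother_education": _block(
            "EA", "mother_education", 6479,
            [(2315, 4348), (839, 1426), (275, 518), (110, 187)],
            (1.26, 1.10, 1.43), (1.15, 0.94, 1.39), (1.42, 1.04, 1.94),
            (1.24, 0.88, 1.76), (1.13, 0.82, 1.56),
            (0.99, 0.68, 1.42, 0.94), (0.02, -0.47, 0.51, 0.47),
        ),
    },
    "AA": {
        "maternal_warmth": _block(
            "AA", "maternal_warmth", 1368,
            [(417, 738), (168, 268), (180, 287), (50, 75)],
            (1.28, 0.90, 1.82), (1.41, 1.00, 1.98), (1.54, 0.86, 2.77),
            (1.09, 0.58, 2.05), (1.20, 0.64, 2.27),
            (0.85, 0.42, 1.76, 0.67), (-0.15, -1.20, 0.90, 0.61),
        ),
        "financial_burden": _block(
            "AA", "financial_burden", 2130,
            [(869, 1502), (308, 489), (63, 95), (27, 44)],
            (1.21, 0.92, 1.58), (1.31, 0.77, 2.22), (1.30, 0.59, 2.87),
            (0.99, 0.39, 2.53), (1.08, 0.48, 2.43),
            (0.82, 0.31, 2.17, 0.69), (-0.21, -1.47, 1.04, 0.63),
        ),
        "childhood_stress": _block(
            "AA", "childhood_stress", 1482,
            [(458, 837), (169, 282), (183, 276), (64, 87)],
            (1.15, 0.81, 1.63), (1.28, 0.90, 1.81), (2.1, 1.17, 3.77),
            (1.64, 0.87, 3.09), (1.82, 0.97, 3.44),
            (1.43, 0.69, 2.94, 0.33), (0.67, -0.61, 1.95, 0.15),
        ),
        "father_education": _block(
            "AA", "father_education", 1277,
            [(527, 890), (198, 339), (24, 41), (4, 7)],
            (1.05, 0.14, 7.79), (1.19, 0.51, 2.76), (1.14, 0.48, 2.73),
            (0.96, 0.71, 1.32), (1.09, 0.17, 6.91),
            (0.77, 0.14, 4.11, 0.76), (-0.3, -2.48, 1.88, 0.61),
        ),
        "mother_education": _block(
            "AA", "mother_education", 1699,
            [(716, 1210), (250, 407), (33, 56), (18, 26)],
            (2.33, 0.63, 8.57), (1.24, 0.66, 2.32), (1.43, 0.74, 2.77),
            (1.16, 0.87, 1.54), (0.61, 0.19, 1.99),
            (0.5, 0.13, 1.88, 0.30), (-1.14, -4.14, 1.87, 0.77),
        ),
    },
}
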