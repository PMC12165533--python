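"""Pathological response labeling under immune-related response criteria.

%irRVT is the residual viable tumor share of the total tumor bed
(regression bed + residual viable tumor + necrosis). Categories:

* pCR  — 0% viable tumor and no lymph-node metastasis,
* MPR  — at most 10% viable tumor (and not pCR),
* pPR  — more than 10% and at most 50%,
* pSD  — more than 50%.

A specimen with 0% viable tumor but nodal metastasis fails the pCR
definition and falls into MPR, the best class containing <=10% — a pinned
convention, since the criteria define only pCR's nodal condition.
Unresected patients with biopsy-proven residual tumor are labeled non-pCR
with the "unresected" flag so they stay in response denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

from .quant import DataError

RESPONSE_CATEGORIES = ("pCR", "MPR", "pPR", "pSD")


class UndefinedScoreError(ValueError):
    pass


@dataclass(frozen=True)
class PathologySpecimen:
    sample_id: str
    viable_area: float
    regression_area: float
    necrosis_area: float
    lymph_node_metastasis: bool = False

    def __post_init__(self):
        for name in ("viable_area", "regression_area", "necrosis_area"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class ResponseLabel:
    sample_id: str
    irrvt_percent: float
    category: str
    is_pcr: bool
    unresected: bool = False

    def __post_init__(self):
        if self.category not in RESPONSE_CATEGORIES:
            raise DataError(f"unknown response category {self.category!r}")


def irrvt_percent(specimen: PathologySpecimen) -> float:
    """100 x viable / (viable + regression + necrosis)."""
    total = (
        specimen.viable_area + specimen.regression_area + specimen.necrosis_area
    )
    if total <= 0:
        raise UndefinedScoreError(
            f"{specimen.sample_id}: total tumor bed area is zero"
        )
    return 100.0 * specimen.viable_area / total


def classify_response(
    irrvt: float,
    lymph_node_metastasis: bool,
    sample_id: str = "",
) -> ResponseLabel:
    """Map %irRVT and nodal status to a four-class response label."""
    if not 0.0 <= irrvt <= 100.0:
        raise DataError(f"%irRVT {irrvt} outside [0, 100]")
    if irrvt == 0.0 and not lymph_node_metastasis:
        category = "pCR"
    elif irrvt <= 10.0:
        category = "MPR"
    elif irrvt <= 50.0:
        category = "pPR"
    else:
        category = "pSD"
    return ResponseLabel(sample_id, irrvt, category, category == "pCR")


def label_specimen(specimen: PathologySpecimen) -> ResponseLabel:
    return classify_response(
        irrvt_percent(specimen),
        specimen.lymph_node_metastasis,
        specimen.sample_id,
    )


def label_unresected(sample_id: str) -> ResponseLabel:
    """Non-pCR label for an unresectable patient with residual tumor on biopsy."""
    return ResponseLabel(sample_id, 100.0, "pSD", False, unresected=True)


def pcr_rate(labels) -> float:
    """Percent of patients achieving pCR (0-100 scale)."""
    labels = list(labels)
    if not labels:
        raise DataError("no labels")
    return 100.0 * sum(l.is_pcr for l in labels) / len(labels)
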