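"""Assign called pseudouridine sites to synthases via knockout libraries.

A site is attributed to a synthase when its peak disappears in that enzyme's
knockout library while remaining present in every other knockout: "absent"
requires (1) sufficient coverage in the knockout window, (2) a knockout peak
Z below ``ko_z_max`` (default 10) and (3) a wild-type CMC Z at least
``ko_fold`` (default 4) times the knockout Z.  Sites absent in two or more
knockouts are ambiguous; sites whose peak is present wherever covered but
with at least one uncovered knockout stay unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .peaks import CallThresholds, ZResult
from .simulate import ENZYMES
from .tracks import SiteCall


@dataclass
class AssignmentResult:
    site: SiteCall
    status: str  # assigned | ambiguous | unassigned
    enzyme: str | None = None
    absent_in: list[str] = field(default_factory=list)
    low_coverage_in: list[str] = field(default_factory=list)


def knockout_absence(
    wt_cmc: ZResult, ko: ZResult, thresholds: CallThresholds = CallThresholds()
) -> str:
    """Classify one knockout library at a WT-called site.

    Returns ``absent``, ``present`` or ``insufficient``.  The three absence
    criteria are conjunctive; a knockout Z <= 0 satisfies the fold condition
    trivially.
    """
    if not ko.covered or ko.z is None:
        return "insufficient"
    if wt_cmc.z is None:
        raise ValueError("wild-type Z undefined for an already-called site")
    if ko.z >= thresholds.ko_z_max:
        return "present"
    if ko.z > 0 and wt_cmc.z < thresholds.ko_fold * ko.z:
        return "present"
    return "absent"


def assign(
    site: SiteCall,
    wt: ZResult,
    kos: Mapping[str, ZResult],
    thresholds: CallThresholds = CallThresholds(),
    expected_enzymes: Sequence[str] = ENZYMES,
) -> AssignmentResult:
    """Assign a called site to an enzyme, or mark it ambiguous/unassigned.

    ``kos`` maps enzyme name to that knockout library's Z at the site.  An
    enzyme missing from ``kos`` altogether counts as lacking coverage (a
    warning case the caller may log); assignment is computed on the available
    set.
    """
    if site.status != "called":
        raise ValueError("assignment requires a called site")
    absent: list[str] = []
    insufficient: list[str] = [e for e in expected_enzymes if e not in kos]
    for enzyme in expected_enzymes:
        if enzyme not in kos:
            continue
        verdict = knockout_absence(wt, kos[enzyme], thresholds)
        if verdict == "absent":
            absent.append(enzyme)
        elif verdict == "insufficient":
            insufficient.append(enzyme)
    if len(absent) >= 2:
        status, enzyme = "ambiguous", None
    elif len(absent) == 1 and not insufficient:
        status, enzyme = "assigned", absent[0]
    else:
        # peak present wherever covered, or a single absence that an
        # uncovered knockout could contradict: not confidently assignable
        status, enzyme = "unassigned", None
    result = AssignmentResult(
        site=site, status=status, enzyme=enzyme,
        absent_in=absent, low_coverage_in=insufficient,
    )
    site.assignment = enzyme if status == "assigned" else status
    return result


def assign_sites(
    calls: Sequence[SiteCall],
    cmc_label: str = "WT-CMC",
    ko_labels: Mapping[str, str] | None = None,
    thresholds: CallThresholds = CallThresholds(),
    expected_enzymes: Sequence[str] = ENZYMES,
) -> list[AssignmentResult]:
    """Assign every called site using Z-scores recorded by a transcriptome scan.

    ``ko_labels`` maps enzyme name to the library label under which the scan
    stored that knockout's Z (default ``d<enzyme>-CMC``).
    """
    from .peaks import zresult_from_call

    if ko_labels is None:
        ko_labels = {e: f"d{e}-CMC" for e in expected_enzymes}
    results = []
    for call in calls:
        if call.status != "called":
            continue
        wt = zresult_from_call(call, cmc_label)
        kos = {
            enz: zresult_from_call(call, lab)
            for enz, lab in ko_labels.items()
            if lab in call.z_by_library or lab in call.covered_by_library
        }
        results.append(assign(call, wt, kos, thresholds,
                              expected_enzymes=list(ko_labels)))
    return results
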