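"""ICE score computation, ICANS grade assembly and inter-rater agreement.

The Immune Effector Cell-Associated Encephalopathy (ICE) score is a 0-10
bedside cognitive assessment: naming (0-3), orientation (0-4), command
following (0-1), attention (0-1) and writing (0-1); 10 is a normal exam.
Retrospective chart review rarely records the canonical items, so a rule
table maps structured exam findings to components, accepting the standard
substitutions (months/days backward or spelling WORLD backward for attention;
state/president/senator for orientation items; "fully alert and oriented" for
full orientation; fluent speech without paraphasic errors for full naming;
absence of aphasia and tremor for the writing point).

The ICANS grade (0-4) combines the ICE score with four other neurological
domains (level of consciousness, motor symptoms, seizures, cerebral edema) by
a max rule, following the ASTCT consensus.  The ICE-band -> grade mapping is
configuration: the consensus defaults shipped here are external clinical
knowledge, editable per site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

# -- ICE ------------------------------------------------------------------

ICE_COMPONENT_MAX = {
    "naming": 3,
    "orientation": 4,
    "command": 1,
    "attention": 1,
    "writing": 1,
}

#: Accepted stand-ins for the canonical four orientation items
#: (year, month, city, hospital).
ORIENTATION_ITEMS = ("year", "month", "city", "hospital")
ORIENTATION_SUBSTITUTES = ("date", "state", "president", "senator")

#: Any passed alternative attention task earns the attention point.
ATTENTION_TASKS = ("serial_10s", "serial_7s", "moyb", "dowb",
                   "world_backward")


@dataclass(frozen=True)
class ICEAssessment:
    """ICE components for one patient-day-reviewer, with substitution notes."""

    naming: int
    orientation: int
    command: int
    attention: int
    writing: int
    notes: tuple[str, ...] = ()

    def __post_init__(self):
        for comp, mx in ICE_COMPONENT_MAX.items():
            v = getattr(self, comp)
            if not (0 <= v <= mx):
                raise ValueError(f"ICE component {comp}={v} outside [0, {mx}]")


def ice_total(a: ICEAssessment) -> int:
    """Total ICE score, 0-10; 10 reflects a normal exam."""
    return a.naming + a.orientation + a.command + a.attention + a.writing


def ice_from_findings(findings: Mapping) -> ICEAssessment:
    """Map structured chart findings to ICE components via the substitution
    rule table.

    Recognised keys (all optional; absent evidence scores 0):

    * ``naming_objects`` (0-3) or ``fluent_speech`` (bool) with optional
      ``language_deficits`` (bool) vetoing the substitution
    * ``oriented_items`` (iterable of item names), or
      ``fully_alert_oriented`` (bool) for the full 4 points
    * ``follows_commands`` (bool)
    * one of the attention tasks (bool pass/fail)
    * ``writing_intact`` (bool) or ``no_aphasia_or_tremor`` (bool)
    """
    notes: list[str] = []

    if "naming_objects" in findings:
        naming = int(findings["naming_objects"])
    elif findings.get("fluent_speech") and not findings.get("language_deficits"):
        naming = 3
        notes.append("naming: full points for fluent speech without deficits")
    else:
        naming = 0

    if findings.get("fully_alert_oriented"):
        orientation = 4
        notes.append("orientation: 'fully alert and oriented' -> 4 points")
    else:
        items = set(findings.get("oriented_items", ()))
        unknown = items - set(ORIENTATION_ITEMS) - set(ORIENTATION_SUBSTITUTES)
        if unknown:
            raise ValueError(f"unknown orientation items: {sorted(unknown)}")
        subs = items & set(ORIENTATION_SUBSTITUTES)
        if subs:
            notes.append(f"orientation: substituted items {sorted(subs)}")
        orientation = min(len(items), ICE_COMPONENT_MAX["orientation"])

    command = 1 if findings.get("follows_commands") else 0

    passed = [t for t in ATTENTION_TASKS if findings.get(t)]
    attention = 1 if passed else 0
    if passed and passed != ["serial_10s"]:
        notes.append(f"attention: credited via {passed[0]}")

    if findings.get("writing_intact"):
        writing = 1
    elif findings.get("no_aphasia_or_tremor"):
        writing = 1
        notes.append("writing: full point for no aphasia or tremor on exam")
    else:
        writing = 0

    return ICEAssessment(naming, orientation, command, attention, writing,
                         tuple(notes))


# -- ICANS ----------------------------------------------------------------

DOMAIN_NAMES = ("consciousness", "motor", "seizure", "edema")


@dataclass(frozen=True)
class NeuroDomains:
    """Ordinal grade contribution (0-4) from each non-ICE neurological domain."""

    consciousness: int = 0
    motor: int = 0
    seizure: int = 0
    edema: int = 0

    def __post_init__(self):
        for name in DOMAIN_NAMES:
            v = getattr(self, name)
            if v not in (0, 1, 2, 3, 4):
                raise ValueError(f"domain {name}={v} outside {{0..4}}")


#: ASTCT consensus ICE-band mapping: (min_ice, max_ice, implied grade).
#: External clinical knowledge, overridable via configuration.
DEFAULT_ICE_BANDS: tuple[tuple[int, int, int], ...] = (
    (10, 10, 0),
    (7, 9, 1),
    (3, 6, 2),
    (0, 2, 3),
)


@dataclass(frozen=True)
class ICANSGrade:
    """Final ICANS grade; half-grades arise from reviewer averaging."""

    value: float
    source: str = "single"   # single | reconciled

    def __post_init__(self):
        if not (0 <= self.value <= 4) or (self.value * 2) % 1 != 0:
            raise ValueError(f"ICANS grade must lie in 0-4 half-steps, "
                             f"got {self.value}")


def icans_grade(ice: int, domains: NeuroDomains,
                ice_bands: Sequence[tuple[int, int, int]] | None = None
                ) -> ICANSGrade:
    """Grade = max(ICE-band implied grade, each domain grade)."""
    if not 0 <= ice <= 10:
        raise ValueError(f"ICE total {ice} outside [0, 10]")
    bands = DEFAULT_ICE_BANDS if ice_bands is None else tuple(ice_bands)
    if not bands:
        raise ValueError("empty ICE band configuration")
    band_grade = None
    for lo, hi, g in bands:
        if lo <= ice <= hi:
            band_grade = g
            break
    if band_grade is None:
        raise ValueError(f"ICE total {ice} not covered by band configuration")
    value = max(band_grade, *(getattr(domains, n) for n in DOMAIN_NAMES))
    return ICANSGrade(float(value))


def reconcile(grades: Sequence[ICANSGrade | float]) -> ICANSGrade:
    """Combine reviewer grades: unanimity passes through, otherwise the
    arithmetic mean (the discrepancy rule)."""
    if len(grades) == 0:
        raise ValueError("no grades to reconcile")
    values = [g.value if isinstance(g, ICANSGrade) else float(g)
              for g in grades]
    if len(set(values)) == 1:
        return ICANSGrade(values[0], source="single")
    return ICANSGrade(float(np.mean(values)), source="reconciled")


# -- inter-rater agreement -------------------------------------------------

def agreement_stats(scores_by_rater, basis: str = "pairwise") -> dict:
    """Inter-rater agreement of scores over a shared item set.

    Parameters
    ----------
    scores_by_rater : array-like, shape (n_raters, n_items)
    basis : ``"pairwise"`` (absolute differences over all rater pairs, the
        default) or ``"consensus"`` (absolute deviations from the per-item
        mean across raters).

    Returns mean and SD (ddof=1) of the absolute deviations and the percent
    of deviations equal to 0, 1, or >= 2 points (half-point deviations are
    binned to the nearest integer class).  The three percentages always sum
    to 100.
    """
    scores = np.asarray(scores_by_rater, dtype=float)
    if scores.ndim != 2 or scores.shape[0] < 2 or scores.shape[1] < 1:
        raise ValueError("need a (raters >= 2) x (items >= 1) score matrix")
    n_raters = scores.shape[0]
    if basis == "pairwise":
        devs = np.concatenate([
            np.abs(scores[i] - scores[j])
            for i in range(n_raters) for j in range(i + 1, n_raters)
        ])
    elif basis == "consensus":
        devs = np.abs(scores - scores.mean(axis=0)).ravel()
    else:
        raise ValueError(f"unknown basis {basis!r}")
    pct0 = 100.0 * np.mean(devs < 0.5)
    pct1 = 100.0 * np.mean((devs >= 0.5) & (devs < 1.5))
    pct2 = 100.0 * np.mean(devs >= 1.5)
    sd = float(np.std(devs, ddof=1)) if devs.size > 1 else 0.0
    return {
        "mad": float(np.mean(devs)),
        "sd": sd,
        "pct_diff_0": float(pct0),
        "pct_diff_1": float(pct1),
        "pct_diff_ge2": float(pct2),
    }
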