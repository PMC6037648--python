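"""Assign fingerprints to GH57 specificity groups and like-protein groups.

Classification follows the family's own logic: the *base* specificity is the
enzyme group whose CSR profiles give the extracted 36-mer the highest total
log-odds, while the catalytic machinery decides between the enzyme group and
its "-like" partner.  A fingerprint with Glu at position 15 and Asp at
position 20 carries the complete machinery; any substitution there marks the
sequence as a presumably non-catalytic like protein.  Diagnostic-position
agreement (positions 1, 12, 23, 35-36) is recorded as corroborating flags and
used only to break exact score ties, never to veto a score-based assignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .detect import ProfileSet
from .schema import (
    ENZYME,
    FINGERPRINT_LENGTH,
    DiagnosticRuleTable,
    FingerprintSchema,
    GroupCatalogue,
    default_catalogue,
    default_rules,
    default_schema,
)
from .synthetic import (
    MACHINERY_COMPLETE,
    MACHINERY_NO_DONOR,
    MACHINERY_NO_NUCLEOPHILE,
    MACHINERY_NONE,
)

UNCLASSIFIED = "unclassified"


def check_catalytic_machinery(fingerprint: str, schema: FingerprintSchema | None = None) -> str:
    """Machinery status of a 36-mer: Glu15 nucleophile and Asp20 proton donor."""
    if len(fingerprint) != FINGERPRINT_LENGTH:
        raise ValueError(f"fingerprint must have length 36, got {len(fingerprint)}")
    schema = schema or default_schema()
    has_nucleophile = fingerprint[schema.nucleophile_pos - 1] == "E"
    has_donor = fingerprint[schema.donor_pos - 1] == "D"
    if has_nucleophile and has_donor:
        return MACHINERY_COMPLETE
    if has_donor:
        return MACHINERY_NO_NUCLEOPHILE
    if has_nucleophile:
        return MACHINERY_NO_DONOR
    return MACHINERY_NONE


def diagnostic_match(
    fingerprint: str, rules: DiagnosticRuleTable | None = None
) -> dict[str, dict[int, bool]]:
    """Per-enzyme-group agreement flags at the diagnostic positions."""
    return (rules or default_rules()).match_fingerprint(fingerprint)


def score_against_groups(
    fingerprint: str, profile_sets: Mapping[str, ProfileSet]
) -> dict[str, float]:
    """Total log-odds of a fingerprint under each group's profile set."""
    return {group: pset.score_fingerprint(fingerprint) for group, pset in profile_sets.items()}


@dataclass(frozen=True)
class GroupAssignment:
    """Classification outcome for one sequence."""

    seq_id: str
    machinery: str
    best_group: str
    label: str
    scores: Mapping[str, float]
    flags: Mapping[str, Mapping[int, bool]]
    warnings: tuple[str, ...] = ()

    @property
    def best_score(self) -> float:
        return self.scores[self.best_group]


def _flag_count(flags: Mapping[int, bool]) -> int:
    return sum(bool(v) for v in flags.values())


def assign(
    fingerprint: str,
    machinery: str,
    scores: Mapping[str, float],
    flags: Mapping[str, Mapping[int, bool]],
    *,
    catalogue: GroupCatalogue | None = None,
    threshold: float = 0.0,
    margin: float | None = None,
    seq_id: str = "",
) -> GroupAssignment:
    """Combine scores, machinery status and diagnostic flags into a label.

    Below-threshold best scores yield ``unclassified``.  Otherwise the label
    is the best base group, moved to its like-protein partner whenever the
    machinery is incomplete.  Score ties are broken by diagnostic-flag count,
    then lexicographic group name.  ``margin`` is accepted for interface
    stability but unused by the default policy.
    """
    del margin  # reserved; like assignment is machinery-driven by default
    catalogue = catalogue or default_catalogue()
    if not scores:
        raise ValueError("scores must cover at least one group")

    best_group = sorted(
        scores, key=lambda g: (-scores[g], -_flag_count(flags.get(g, {})), g)
    )[0]
    warnings: list[str] = []
    if scores[best_group] < threshold:
        label = UNCLASSIFIED
    elif machinery != MACHINERY_COMPLETE:
        like = catalogue.like_of(best_group)
        if like is None:
            label = best_group
            warnings.append(f"incomplete machinery but {best_group} has no like-protein group")
        else:
            label = like
    else:
        label = best_group

    if label not in (UNCLASSIFIED,):
        group_flags = flags.get(best_group, {})
        disagreements = [pos for pos, ok in group_flags.items() if not ok]
        if disagreements:
            warnings.append(
                f"diagnostic disagreement with {best_group} at position(s) "
                + ",".join(str(p) for p in disagreements)
            )
    return GroupAssignment(
        seq_id=seq_id,
        machinery=machinery,
        best_group=best_group,
        label=label,
        scores=dict(scores),
        flags={g: dict(f) for g, f in flags.items()},
        warnings=tuple(warnings),
    )


def classify_fingerprint(
    seq_id: str,
    fingerprint: str,
    profile_sets: Mapping[str, ProfileSet],
    *,
    catalogue: GroupCatalogue | None = None,
    rules: DiagnosticRuleTable | None = None,
    schema: FingerprintSchema | None = None,
    threshold: float = 0.0,
) -> GroupAssignment:
    """Convenience wrapper: machinery + flags + scores + assignment in one call."""
    machinery = check_catalytic_machinery(fingerprint, schema)
    flags = diagnostic_match(fingerprint, rules)
    scores = score_against_groups(fingerprint, profile_sets)
    return assign(
        fingerprint, machinery, scores, flags,
        catalogue=catalogue, threshold=threshold, seq_id=seq_id,
    )


def assignments_frame(assignments: Iterable[GroupAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments:
        rows.append(
            {
                "id": a.seq_id,
                "machinery": a.machinery,
                "best_group": a.best_group,
                "label": a.label,
                "score": a.best_score,
                "flags_true": _flag_count(a.flags.get(a.best_group, {})),
                "warnings": ";".join(a.warnings),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["id", "machinery", "best_group", "label", "score", "flags_true", "warnings"],
    )


@dataclass(frozen=True)
class SummaryReport:
    """Table-style bookkeeping of one classification run."""

    per_group: pd.DataFrame  # group, total, archaeal, bacterial
    unclassified: int
    eliminated: int
    total_input: int

    @property
    def classified(self) -> int:
        return int(self.per_group["total"].sum())


def summarize(
    assignments: Sequence[GroupAssignment],
    taxonomy_labels: Mapping[str, str] | None = None,
    *,
    eliminated: int = 0,
    catalogue: GroupCatalogue | None = None,
) -> SummaryReport:
    """Per-group and per-taxon counts; totals reconcile with the input size."""
    catalogue = catalogue or default_catalogue()
    taxonomy_labels = taxonomy_labels or {}
    counts: dict[str, dict[str, int]] = {
        g: {"total": 0, "archaeal": 0, "bacterial": 0} for g in catalogue.names
    }
    unclassified = 0
    for a in assignments:
        if a.label == UNCLASSIFIED:
            unclassified += 1
            continue
        row = counts.setdefault(a.label, {"total": 0, "archaeal": 0, "bacterial": 0})
        row["total"] += 1
        tax = taxonomy_labels.get(a.seq_id)
        if tax in ("archaeal", "bacterial"):
            row[tax] += 1
    per_group = pd.DataFrame(
        [{"group": g, **row} for g, row in counts.items()],
        columns=["group", "total", "archaeal", "bacterial"],
    )
    return SummaryReport(
        per_group=per_group,
        unclassified=unclassified,
        eliminated=eliminated,
        total_input=len(assignments) + eliminated,
    )
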