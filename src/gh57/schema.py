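"""Fixed fingerprint layout, group catalogue and diagnostic rules for family GH57.

Family GH57 is the "second" alpha-amylase family: its members share five short
conserved sequence regions (CSR-1..CSR-5) while being unalignable over their
full lengths.  Concatenating the five CSRs yields a 36-position *fingerprint*
on which every downstream stage of this package operates:

* positions 1-5   -> CSR-1
* positions 6-11  -> CSR-2
* positions 12-17 -> CSR-3 (catalytic nucleophile, Glu, at position 15)
* positions 18-27 -> CSR-4 (proton donor, Asp, at position 20)
* positions 28-36 -> CSR-5

A handful of *diagnostic* fingerprint positions (1, 12, 23, 35, 36) carry
residues that discriminate the enzyme specificities of the family, e.g. the
two tyrosines at 35-36 typical of alpha-amylases, or the invariant
glycine-tryptophan pair of alpha-galactosidases.

This module holds the fixed layout (:class:`FingerprintSchema`), the study
catalogue of 14 specificity / "like"-protein groups with their taxonomy and
length statistics (:class:`GroupCatalogue`), and the per-group diagnostic
residue rules (:class:`DiagnosticRuleTable`).  All of it is loaded from a
versioned JSON document shipped as package data, so an alternative family
could be configured without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterator, Mapping

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
#: Residues treated as "aromatic" by the residue-class rules.  Histidine is
#: included conservatively alongside Phe/Trp/Tyr.
AROMATIC = frozenset("FWYH")
FINGERPRINT_LENGTH = 36

ENZYME = "enzyme"
LIKE = "like-protein"

_DEFINITION_RESOURCE = "gh57_definition.json"


class SchemaError(ValueError):
    """A fingerprint layout, catalogue or rule table violates its invariants."""


def residue_rule_matches(rule: str, residue: str) -> bool:
    """Evaluate one diagnostic residue rule against a single residue.

    Rules are either an alternation of exact residues (``"T"``, ``"K|H"``),
    the class ``"aromatic"`` (F/W/Y/H) or its complement ``"!aromatic"``
    (any standard residue that is not aromatic).
    """
    if rule == "aromatic":
        return residue in AROMATIC
    if rule == "!aromatic":
        return residue in AA_INDEX and residue not in AROMATIC
    return residue in rule.split("|")


@dataclass(frozen=True)
class FingerprintSchema:
    """The fixed 36-position CSR layout of the GH57 fingerprint."""

    csr_spans: tuple[tuple[int, int], ...] = ((1, 5), (6, 11), (12, 17), (18, 27), (28, 36))
    nucleophile_pos: int = 15
    donor_pos: int = 20
    diagnostic_positions: tuple[int, ...] = (1, 12, 23, 35, 36)

    def __post_init__(self) -> None:
        if len(self.csr_spans) != 5:
            raise SchemaError("fingerprint layout requires exactly five CSR spans")
        covered: list[int] = []
        prev_end = 0
        for start, end in self.csr_spans:
            if start != prev_end + 1 or end < start:
                raise SchemaError("CSR spans must be contiguous, ordered and non-overlapping")
            covered.extend(range(start, end + 1))
            prev_end = end
        if covered != list(range(1, FINGERPRINT_LENGTH + 1)):
            raise SchemaError("CSR spans must cover positions 1..36 exactly")
        for pos in (self.nucleophile_pos, self.donor_pos, *self.diagnostic_positions):
            if not 1 <= pos <= FINGERPRINT_LENGTH:
                raise SchemaError(f"position {pos} outside the fingerprint")
        if not self.csr_spans[2][0] <= self.nucleophile_pos <= self.csr_spans[2][1]:
            raise SchemaError("catalytic nucleophile must lie in CSR-3")
        if not self.csr_spans[3][0] <= self.donor_pos <= self.csr_spans[3][1]:
            raise SchemaError("proton donor must lie in CSR-4")

    @property
    def widths(self) -> tuple[int, ...]:
        """Widths of CSR-1..CSR-5 (5, 6, 6, 10, 9)."""
        return tuple(end - start + 1 for start, end in self.csr_spans)

    @property
    def catalytic_positions(self) -> tuple[int, int]:
        return (self.nucleophile_pos, self.donor_pos)

    @property
    def free_positions(self) -> tuple[int, ...]:
        """Fingerprint positions that are neither catalytic nor diagnostic."""
        fixed = set(self.catalytic_positions) | set(self.diagnostic_positions)
        return tuple(p for p in range(1, FINGERPRINT_LENGTH + 1) if p not in fixed)

    def position_to_csr(self, pos: int) -> tuple[int, int]:
        """Map a fingerprint position to ``(csr_index, offset)``, both 1-based."""
        if not isinstance(pos, int) or not 1 <= pos <= FINGERPRINT_LENGTH:
            raise SchemaError(f"fingerprint position must be in 1..36, got {pos!r}")
        for idx, (start, end) in enumerate(self.csr_spans, start=1):
            if start <= pos <= end:
                return idx, pos - start + 1
        raise SchemaError(f"position {pos} not covered by any CSR")  # pragma: no cover


def logo_position_to_csr(pos: int, schema: FingerprintSchema | None = None) -> tuple[int, int]:
    """Locate a logo (fingerprint) position within the five CSRs.

    Returns the 1-based CSR index and the 1-based offset within that CSR,
    e.g. the catalytic nucleophile, position 15, maps to ``(3, 4)``.
    """
    return (schema or default_schema()).position_to_csr(pos)


@dataclass(frozen=True)
class GroupInfo:
    """One row of the study catalogue: a specificity or like-protein group."""

    name: str
    full_name: str
    kind: str
    partner: str | None
    archaea: int
    bacteria: int
    characterized: int
    mean_length: int

    def __post_init__(self) -> None:
        if self.kind not in (ENZYME, LIKE):
            raise SchemaError(f"unknown group kind {self.kind!r}")
        if (self.kind == LIKE) != (self.partner is not None):
            raise SchemaError(f"group {self.name}: exactly the like groups name a base partner")
        if min(self.archaea, self.bacteria, self.characterized, self.mean_length) < 0:
            raise SchemaError(f"group {self.name}: negative count")

    @property
    def members(self) -> int:
        return self.archaea + self.bacteria


@dataclass(frozen=True)
class GroupCatalogue:
    """The 14 GH57 groups with member counts, taxonomy split and mean lengths.

    Note on homogeneity: the like-protein groups are documented as not
    perfectly homogeneous in the wild (a minority of members retain the full
    catalytic machinery); the catalogue records group bookkeeping only and
    encodes no rule about individual members.
    """

    groups: tuple[GroupInfo, ...]
    _by_name: Mapping[str, GroupInfo] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        by_name = {g.name: g for g in self.groups}
        if len(by_name) != len(self.groups):
            raise SchemaError("duplicate group names in catalogue")
        for g in self.groups:
            if g.partner is not None:
                base = by_name.get(g.partner)
                if base is None or base.kind != ENZYME:
                    raise SchemaError(f"like group {g.name} must name an enzyme base group")
        object.__setattr__(self, "_by_name", by_name)

    def __iter__(self) -> Iterator[GroupInfo]:
        return iter(self.groups)

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def __getitem__(self, name: str) -> GroupInfo:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"unknown GH57 group {name!r}") from None

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups)

    @property
    def enzyme_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups if g.kind == ENZYME)

    @property
    def like_names(self) -> tuple[str, ...]:
        return tuple(g.name for g in self.groups if g.kind == LIKE)

    def counts(self) -> dict[str, int]:
        return {g.name: g.members for g in self.groups}

    def base_of(self, name: str) -> str:
        """Base enzyme group of ``name`` (identity for enzyme groups)."""
        info = self[name]
        return info.partner if info.partner is not None else info.name

    def like_of(self, enzyme_name: str) -> str | None:
        """The like-protein partner of an enzyme group, if one exists."""
        for g in self.groups:
            if g.partner == enzyme_name:
                return g.name
        return None

    @property
    def total_members(self) -> int:
        return sum(g.members for g in self.groups)

    @property
    def total_archaea(self) -> int:
        return sum(g.archaea for g in self.groups)

    @property
    def total_bacteria(self) -> int:
        return sum(g.bacteria for g in self.groups)

    @property
    def total_characterized(self) -> int:
        return sum(g.characterized for g in self.groups)


@dataclass(frozen=True)
class DiagnosticRuleTable:
    """Expected residues at the diagnostic fingerprint positions, per group.

    Maps enzyme-group name -> {position -> residue rule}.  Rules are flags
    used for corroboration, never a hard veto: the family's growth has eroded
    the absolute uniqueness of several of these residues.
    """

    rules: Mapping[str, Mapping[int, str]]

    def __post_init__(self) -> None:
        frozen = {g: dict(sorted(pr.items())) for g, pr in self.rules.items()}
        object.__setattr__(self, "rules", frozen)

    @property
    def group_names(self) -> tuple[str, ...]:
        return tuple(self.rules)

    def positions_used(self) -> frozenset[int]:
        return frozenset(p for pr in self.rules.values() for p in pr)

    def expected(self, group: str) -> Mapping[int, str]:
        try:
            return self.rules[group]
        except KeyError:
            raise KeyError(f"no diagnostic rules for group {group!r}") from None

    def validate_against(self, schema: FingerprintSchema, catalogue: GroupCatalogue) -> None:
        missing = self.positions_used() - set(schema.diagnostic_positions)
        if missing:
            raise SchemaError(f"rule positions {sorted(missing)} not declared diagnostic")
        for group in self.rules:
            if group not in catalogue or catalogue[group].kind != ENZYME:
                raise SchemaError(f"diagnostic rules refer to unknown enzyme group {group!r}")

    def match_fingerprint(self, fingerprint: str) -> dict[str, dict[int, bool]]:
        """Per-group, per-position agreement flags for one 36-mer."""
        if len(fingerprint) != FINGERPRINT_LENGTH:
            raise ValueError(f"fingerprint must have length 36, got {len(fingerprint)}")
        return {
            group: {pos: residue_rule_matches(rule, fingerprint[pos - 1]) for pos, rule in pr.items()}
            for group, pr in self.rules.items()
        }


# --- JSON document (package data) -------------------------------------------

@lru_cache(maxsize=1)
def _default_document() -> dict:
    with resources.files("gh57.data").joinpath(_DEFINITION_RESOURCE).open() as fh:
        return json.load(fh)


def from_document(doc: Mapping) -> tuple[FingerprintSchema, GroupCatalogue, DiagnosticRuleTable]:
    """Deserialize the (schema, catalogue, rules) triple from a JSON document."""
    if doc.get("format_version") != 1:
        raise SchemaError(f"unsupported definition format_version {doc.get('format_version')!r}")
    fp = doc["fingerprint"]
    schema = FingerprintSchema(
        csr_spans=tuple((int(a), int(b)) for a, b in fp["csr_spans"]),
        nucleophile_pos=int(fp["nucleophile_pos"]),
        donor_pos=int(fp["donor_pos"]),
        diagnostic_positions=tuple(int(p) for p in fp["diagnostic_positions"]),
    )
    catalogue = GroupCatalogue(tuple(GroupInfo(**g) for g in doc["groups"]))
    rules = DiagnosticRuleTable(
        {g: {int(p): r for p, r in pr.items()} for g, pr in doc["diagnostic_rules"].items()}
    )
    rules.validate_against(schema, catalogue)
    return schema, catalogue, rules


def to_document(
    schema: FingerprintSchema, catalogue: GroupCatalogue, rules: DiagnosticRuleTable
) -> dict:
    """Serialize the triple back to the versioned JSON document form."""
    return {
        "format_version": 1,
        "family": "GH57",
        "fingerprint": {
            "length": FINGERPRINT_LENGTH,
            "csr_spans": [list(span) for span in schema.csr_spans],
            "nucleophile_pos": schema.nucleophile_pos,
            "donor_pos": schema.donor_pos,
            "diagnostic_positions": list(schema.diagnostic_positions),
        },
        "groups": [
            {
                "name": g.name,
                "full_name": g.full_name,
                "kind": g.kind,
                "partner": g.partner,
                "archaea": g.archaea,
                "bacteria": g.bacteria,
                "characterized": g.characterized,
                "mean_length": g.mean_length,
            }
            for g in catalogue
        ],
        "diagnostic_rules": {g: {str(p): r for p, r in pr.items()} for g, pr in rules.rules.items()},
    }


def default_schema() -> FingerprintSchema:
    """The fixed GH57 fingerprint layout (CSR spans 1-5/6-11/12-17/18-27/28-36)."""
    return from_document(_default_document())[0]


def default_catalogue() -> GroupCatalogue:
    """The 14-group study catalogue (1602 members: 383 archaeal, 1219 bacterial)."""
    return from_document(_default_document())[1]


def default_rules() -> DiagnosticRuleTable:
    """Diagnostic residue expectations at positions 1, 12, 23 and 35-36."""
    return from_document(_default_document())[2]


def load_definition(path) -> tuple[FingerprintSchema, GroupCatalogue, DiagnosticRuleTable]:
    """Load a (schema, catalogue, rules) triple from a user JSON file."""
    with open(path) as fh:
        return from_document(json.load(fh))


def dump_definition(path, schema, catalogue, rules) -> None:
    with open(path, "w") as fh:
        json.dump(to_document(schema, catalogue, rules), fh, indent=2)
        fh.write("\n")
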