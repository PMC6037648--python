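"""Synthetic GH57-like datasets with the statistical structure of the study set.

The generator emits labeled protein sequences in which the five CSRs are
embedded in random linker sequence.  It reproduces the bookkeeping of the real
1602-sequence collection: the 14 group sizes, their archaeal/bacterial splits
and mean lengths, per-group 36-position fingerprints with the catalytic Glu15
/ Asp20 pair and the documented diagnostic residues, plus "like"-protein
variants whose nucleophile and/or proton donor has been substituted.  A small
configurable fraction of decoy sequences with one CSR deleted exercises the
elimination rule of the detection stage.

The model is deliberately simple: fingerprint positions mutate away from the
group consensus i.i.d. with probability ``1 - conservation``; linkers are
i.i.d. background residues; no phylogenetic correlation structure within
groups is simulated.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .schema import (
    AA_ALPHABET,
    ENZYME,
    FINGERPRINT_LENGTH,
    AROMATIC,
    DiagnosticRuleTable,
    FingerprintSchema,
    GroupCatalogue,
    default_catalogue,
    default_rules,
    default_schema,
)

MACHINERY_COMPLETE = "complete"
MACHINERY_NO_NUCLEOPHILE = "nucleophile-substituted"
MACHINERY_NO_DONOR = "donor-substituted"
MACHINERY_NONE = "both-substituted"

KNOCKOUT_MODES = ("nucleophile", "donor", "both")
#: Sampling weights for the three knockout modes; losing a single catalytic
#: residue is the common case, losing both the rare one.
_KNOCKOUT_WEIGHTS = (0.45, 0.45, 0.10)

#: Minimum number of free-position differences enforced between the consensi
#: of any two distinct enzyme groups.
MIN_GROUP_DIVERGENCE = 8

ARCHAEAL = "archaeal"
BACTERIAL = "bacterial"


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    ``counts`` defaults to the 14 group sizes of the study catalogue (1602
    sequences in total).  ``conservation`` is the probability that a
    non-diagnostic fingerprint position matches its group consensus.
    ``length_jitter`` is the fractional standard deviation of total sequence
    length around the group mean.  ``dropout_fraction`` of additional decoy
    sequences are generated with one CSR deleted.
    """

    seed: int = 1602
    counts: Mapping[str, int] | None = None
    conservation: float = 0.9
    linker_composition: Sequence[float] | None = None
    length_jitter: float = 0.05
    dropout_fraction: float = 0.02
    min_spacer: int = 5
    like_consensus_divergence: int = 10

    def __post_init__(self) -> None:
        if not 0.0 < self.conservation <= 1.0:
            raise ValueError("conservation must lie in (0, 1]")
        if self.counts is not None and any(n < 0 for n in self.counts.values()):
            raise ValueError("group counts must be non-negative")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must lie in [0, 1)")
        if self.length_jitter < 0 or self.min_spacer < 1:
            raise ValueError("length_jitter must be >= 0 and min_spacer >= 1")
        if self.linker_composition is not None:
            comp = np.asarray(self.linker_composition, dtype=float)
            if comp.shape != (20,) or comp.min() < 0 or not np.isclose(comp.sum(), 1.0):
                raise ValueError("linker_composition must be 20 probabilities summing to 1")

    def linker_probs(self) -> np.ndarray:
        if self.linker_composition is None:
            return np.full(20, 1 / 20)
        return np.asarray(self.linker_composition, dtype=float)


@dataclass(frozen=True)
class LabeledSequence:
    """One synthetic protein with its ground truth."""

    id: str
    sequence: str
    group: str
    taxonomy: str
    machinery: str
    csr_ranges: tuple[tuple[int, int], ...] | None  # 1-based inclusive; None for decoys
    fingerprint: str
    decoy: bool = False
    missing_csr: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty sequence")
        if self.csr_ranges is not None:
            prev_end = 0
            for start, end in self.csr_ranges:
                if start <= prev_end or end < start or end > len(self.sequence):
                    raise ValueError(f"{self.id}: CSR ranges must be ordered and in-sequence")
                prev_end = end
            if len(self.extracted_fingerprint()) != FINGERPRINT_LENGTH:
                raise ValueError(f"{self.id}: CSR ranges do not span 36 residues")

    def extracted_fingerprint(self) -> str:
        """Concatenate the residues under the recorded CSR ranges."""
        if self.csr_ranges is None:
            raise ValueError(f"{self.id}: decoy sequence has no CSR coordinates")
        return "".join(self.sequence[s - 1 : e] for s, e in self.csr_ranges)


def _consensus_residue_for_rule(rule: str, rng: np.random.Generator) -> str:
    """Deterministic-enough consensus residue satisfying a diagnostic rule."""
    if rule == "aromatic":
        return "W"  # almost exclusively tryptophan in the family
    if rule == "!aromatic":
        non_aromatic = [aa for aa in AA_ALPHABET if aa not in AROMATIC]
        return str(rng.choice(non_aromatic))
    return rule.split("|")[0]


def build_group_consensus(
    catalogue: GroupCatalogue | None = None,
    rules: DiagnosticRuleTable | None = None,
    seed: int = 1602,
    schema: FingerprintSchema | None = None,
    like_divergence: int = 10,
) -> dict[str, str]:
    """Draw one 36-residue consensus per group.

    Enzyme groups carry Glu at the nucleophile position and Asp at the donor
    position, the diagnostic residues their rules dictate, and free positions
    drawn uniformly at random (fixed by ``seed``); draws are repeated until
    every pair of enzyme groups differs at >= 8 of the 29 free positions.
    Each like-protein group receives its base group's consensus with
    ``like_divergence`` free positions substituted, so that like groups are
    closely related to, yet separable from, their base group; their catalytic
    pair stays intact here (knockouts are applied per sequence).
    """
    schema = schema or default_schema()
    catalogue = catalogue or default_catalogue()
    rules = rules or default_rules()
    missing = [g for g in catalogue.enzyme_names if g not in rules.rules]
    if missing:
        raise ValueError(f"diagnostic rules must cover all enzyme groups; missing {missing}")
    rng = np.random.default_rng(seed)
    free = schema.free_positions
    aa = np.array(list(AA_ALPHABET))

    def draw(group: str) -> np.ndarray:
        cons = rng.choice(aa, size=FINGERPRINT_LENGTH)
        cons[schema.nucleophile_pos - 1] = "E"
        cons[schema.donor_pos - 1] = "D"
        for pos, rule in rules.expected(group).items():
            cons[pos - 1] = _consensus_residue_for_rule(rule, rng)
        return cons

    consensi: dict[str, np.ndarray] = {}
    for group in catalogue.enzyme_names:
        candidate = draw(group)
        for _ in range(1000):
            diffs = [
                sum(candidate[p - 1] != other[p - 1] for p in free) for other in consensi.values()
            ]
            if all(d >= MIN_GROUP_DIVERGENCE for d in diffs):
                break
            candidate = draw(group)
        else:  # pragma: no cover - would need a pathological rule table
            raise ValueError(f"could not draw a sufficiently distinct consensus for {group}")
        consensi[group] = candidate

    result = {g: "".join(c) for g, c in consensi.items()}
    for like in catalogue.like_names:
        base = consensi[catalogue.base_of(like)].copy()
        mutated = rng.choice(len(free), size=min(like_divergence, len(free)), replace=False)
        for idx in mutated:
            pos = free[idx]
            current = base[pos - 1]
            choices = [x for x in AA_ALPHABET if x != current]
            base[pos - 1] = rng.choice(choices)
        result[like] = "".join(base)
    return result


def _sample_taxonomy(group: str, catalogue: GroupCatalogue, rng: np.random.Generator) -> str:
    info = catalogue[group]
    if info.members == 0:
        return BACTERIAL
    return ARCHAEAL if rng.random() < info.archaea / info.members else BACTERIAL


def emit_sequence(
    group: str,
    consensus: Mapping[str, str],
    config: SyntheticConfig,
    rng: np.random.Generator,
    *,
    seq_id: str | None = None,
    taxonomy: str | None = None,
    catalogue: GroupCatalogue | None = None,
    schema: FingerprintSchema | None = None,
) -> LabeledSequence:
    """Sample one labeled sequence of ``group`` with its CSRs embedded in linker.

    The fingerprint is the group consensus with i.i.d. substitutions at free
    positions (probability ``1 - conservation``); catalytic and diagnostic
    positions are never flipped.  Total length is Normal(group mean,
    jitter * mean), clamped to fit the five CSRs with minimum spacers; the
    slack is apportioned over N-terminus, four spacers and C-terminus by a
    symmetric Dirichlet draw.
    """
    schema = schema or default_schema()
    catalogue = catalogue or default_catalogue()
    info = catalogue[group]
    cons = consensus[group]
    if len(cons) != FINGERPRINT_LENGTH:
        raise ValueError(f"consensus for {group} must have length 36")

    fp = list(cons)
    for pos in schema.free_positions:
        if rng.random() > config.conservation:
            current = fp[pos - 1]
            fp[pos - 1] = str(rng.choice([x for x in AA_ALPHABET if x != current]))
    fingerprint = "".join(fp)

    min_len = FINGERPRINT_LENGTH + 5 * config.min_spacer
    length = int(round(rng.normal(info.mean_length, config.length_jitter * info.mean_length)))
    length = max(length, min_len)

    slack = length - FINGERPRINT_LENGTH - 4 * config.min_spacer
    shares = rng.dirichlet(np.ones(6))
    seg = np.floor(shares * slack).astype(int)
    for _ in range(slack - int(seg.sum())):  # hand out rounding remainder
        seg[int(rng.integers(0, 6))] += 1
    spacers = [int(s) for s in seg]
    for i in (1, 2, 3, 4):  # internal spacers keep the minimum
        spacers[i] += config.min_spacer

    aa = np.array(list(AA_ALPHABET))
    probs = config.linker_probs()

    def linker(n: int) -> str:
        return "".join(rng.choice(aa, size=n, p=probs)) if n else ""

    widths = schema.widths
    parts: list[str] = []
    ranges: list[tuple[int, int]] = []
    cursor = 0
    offset = 0
    for k in range(5):
        parts.append(linker(spacers[k]))
        cursor += spacers[k]
        parts.append(fingerprint[offset : offset + widths[k]])
        ranges.append((cursor + 1, cursor + widths[k]))
        cursor += widths[k]
        offset += widths[k]
    parts.append(linker(spacers[5]))
    sequence = "".join(parts)

    return LabeledSequence(
        id=seq_id or f"{group}_{rng.integers(10**8):08d}",
        sequence=sequence,
        group=group,
        taxonomy=taxonomy or _sample_taxonomy(group, catalogue, rng),
        machinery=MACHINERY_COMPLETE,
        csr_ranges=tuple(ranges),
        fingerprint=fingerprint,
    )


def knock_out_catalytics(
    seq: LabeledSequence,
    mode: str,
    rng: np.random.Generator,
    *,
    catalogue: GroupCatalogue | None = None,
    schema: FingerprintSchema | None = None,
) -> LabeledSequence:
    """Substitute the catalytic nucleophile and/or proton donor of ``seq``.

    The sequence must still carry the complete machinery.  Its label moves to
    the like-protein partner of its base group; the machinery status records
    which residue(s) were lost.
    """
    if mode not in KNOCKOUT_MODES:
        raise ValueError(f"knockout mode must be one of {KNOCKOUT_MODES}, got {mode!r}")
    if seq.machinery != MACHINERY_COMPLETE:
        raise ValueError(f"{seq.id}: catalytic machinery already incomplete")
    schema = schema or default_schema()
    catalogue = catalogue or default_catalogue()
    base = catalogue.base_of(seq.group)
    like = catalogue.like_of(base)
    if like is None:
        raise ValueError(f"group {base} has no like-protein partner group")

    fp = list(seq.fingerprint)
    chars = list(seq.sequence)
    fp_to_seq = {}
    offset = 0
    for (start, _end), width in zip(seq.csr_ranges, schema.widths):
        for w in range(width):
            fp_to_seq[offset + w + 1] = start + w
        offset += width

    def substitute(pos: int, keep_out: str) -> None:
        new = str(rng.choice([x for x in AA_ALPHABET if x != keep_out]))
        fp[pos - 1] = new
        chars[fp_to_seq[pos] - 1] = new

    if mode in ("nucleophile", "both"):
        substitute(schema.nucleophile_pos, "E")
    if mode in ("donor", "both"):
        substitute(schema.donor_pos, "D")
    status = {
        "nucleophile": MACHINERY_NO_NUCLEOPHILE,
        "donor": MACHINERY_NO_DONOR,
        "both": MACHINERY_NONE,
    }[mode]
    return replace(
        seq,
        sequence="".join(chars),
        fingerprint="".join(fp),
        group=like,
        machinery=status,
    )


@dataclass
class SyntheticDataset:
    """A generated dataset: labeled sequences plus the consensus map used."""

    sequences: list[LabeledSequence]
    config: SyntheticConfig
    consensus: Mapping[str, str]
    schema: FingerprintSchema = field(default_factory=default_schema)

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def non_decoys(self) -> list[LabeledSequence]:
        return [s for s in self.sequences if not s.decoy]

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.sequences:
            row: dict = {
                "id": s.id,
                "group": s.group,
                "taxonomy": s.taxonomy,
                "machinery": s.machinery,
                "decoy": int(s.decoy),
                "missing_csr": "" if s.missing_csr is None else s.missing_csr,
            }
            for k in range(5):
                start, end = s.csr_ranges[k] if s.csr_ranges else ("", "")
                row[f"csr{k + 1}_start"] = start
                row[f"csr{k + 1}_end"] = end
            row["fingerprint"] = s.fingerprint
            rows.append(row)
        return pd.DataFrame(rows)

    def to_fasta(self) -> str:
        buf = io.StringIO()
        for s in self.sequences:
            buf.write(f">{s.id}\n")
            for i in range(0, len(s.sequence), 60):
                buf.write(s.sequence[i : i + 60] + "\n")
        return buf.getvalue()

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_fasta())

    def write_truth(self, path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.truth_table().to_csv(fh, sep="\t", index=False)


def generate_dataset(
    config: SyntheticConfig | None = None,
    *,
    catalogue: GroupCatalogue | None = None,
    rules: DiagnosticRuleTable | None = None,
    schema: FingerprintSchema | None = None,
) -> SyntheticDataset:
    """Generate a full labeled dataset under ``config`` (deterministic in seed).

    Enzyme-group members keep the complete Glu15/Asp20 machinery; every member
    of a like group has one or both catalytic residues substituted.  Taxonomy
    labels hit the catalogue's archaeal/bacterial counts exactly when the
    default counts are used, and pro-rata otherwise.  Decoy sequences (one CSR
    deleted, ``dropout_fraction`` of the total) are appended and flagged.
    """
    config = config or SyntheticConfig()
    schema = schema or default_schema()
    catalogue = catalogue or default_catalogue()
    rules = rules or default_rules()
    counts = dict(config.counts) if config.counts is not None else catalogue.counts()
    unknown = [g for g in counts if g not in catalogue]
    if unknown:
        raise ValueError(f"counts refer to unknown groups {unknown}")

    consensus = build_group_consensus(
        catalogue, rules, seed=config.seed, schema=schema,
        like_divergence=config.like_consensus_divergence,
    )
    rng = np.random.default_rng(config.seed)
    sequences: list[LabeledSequence] = []

    for info in catalogue:
        n = counts.get(info.name, 0)
        if n == 0:
            continue
        if info.members:
            n_arch = int(round(n * info.archaea / info.members))
        else:
            n_arch = 0
        taxonomies = [ARCHAEAL] * n_arch + [BACTERIAL] * (n - n_arch)
        for i in range(n):
            seq = emit_sequence(
                info.name, consensus, config, rng,
                seq_id=f"{info.name}|{i + 1:04d}",
                taxonomy=taxonomies[i],
                catalogue=catalogue, schema=schema,
            )
            if info.kind != ENZYME:
                mode = KNOCKOUT_MODES[rng.choice(3, p=_KNOCKOUT_WEIGHTS)]
                seq = knock_out_catalytics(seq, mode, rng, catalogue=catalogue, schema=schema)
            sequences.append(seq)

    n_total = sum(counts.get(g.name, 0) for g in catalogue)
    n_decoys = int(round(config.dropout_fraction * n_total))
    if n_decoys and n_total:
        names = [g.name for g in catalogue if counts.get(g.name, 0) > 0]
        weights = np.array([counts[g] for g in names], dtype=float)
        weights /= weights.sum()
        for i in range(n_decoys):
            group = str(rng.choice(names, p=weights))
            seq = emit_sequence(
                group, consensus, config, rng,
                seq_id=f"DECOY|{i + 1:04d}",
                catalogue=catalogue, schema=schema,
            )
            drop = int(rng.integers(1, 6))
            start, end = seq.csr_ranges[drop - 1]
            truncated = seq.sequence[: start - 1] + seq.sequence[end:]
            sequences.append(
                LabeledSequence(
                    id=seq.id,
                    sequence=truncated,
                    group=group,
                    taxonomy=seq.taxonomy,
                    machinery=seq.machinery,
                    csr_ranges=None,
                    fingerprint=seq.fingerprint,
                    decoy=True,
                    missing_csr=drop,
                )
            )

    return SyntheticDataset(sequences=sequences, config=config, consensus=consensus, schema=schema)
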