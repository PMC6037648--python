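"""CSR detection: profile scanning, constrained placement, fingerprint extraction.

Each of the five CSRs is modelled as a position-specific scoring profile
(log-odds over the 20-residue alphabet versus a background distribution),
trained from a set of 36-position fingerprints.  Given a query protein, the
five windows are placed simultaneously by exact dynamic programming over all
ordered, non-overlapping placements with a minimum inter-CSR spacer; the
placement maximising the total log-odds wins, with ties broken toward the
leftmost (lexicographically smallest) start tuple.

Sequences in which any CSR's best in-placement score falls below a floor
(a fixed fraction of that profile's own consensus score) are eliminated, the
package's operational version of discarding sequences that obviously lack one
of the five regions.  Residues outside the 20-letter alphabet (X, B, Z, U,
...) score as the background expectation, i.e. log-odds 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .schema import AA_ALPHABET, AA_INDEX, FINGERPRINT_LENGTH, FingerprintSchema, default_schema

_UNKNOWN = 20  # index used for non-standard residues


class DetectionError(ValueError):
    """Invalid input to profile construction or CSR placement."""


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode residues as alphabet indices; non-standard residues map to 20."""
    return np.array([AA_INDEX.get(ch, _UNKNOWN) for ch in sequence.upper()], dtype=np.int64)


@dataclass(frozen=True)
class CSRProfile:
    """Positional residue frequencies and log-odds for one CSR."""

    csr_index: int
    frequencies: np.ndarray  # (width, 20), rows sum to 1
    pseudocount: float
    background: np.ndarray  # (20,)
    _log_odds: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if freq.ndim != 2 or freq.shape[1] != 20 or bg.shape != (20,):
            raise DetectionError("profile frequencies must be (width, 20) with a (20,) background")
        if not np.allclose(freq.sum(axis=1), 1.0):
            raise DetectionError("profile frequencies must sum to 1 per position")
        lo = np.zeros((freq.shape[0], 21))
        lo[:, :20] = np.log2(freq / bg)  # unknown residues keep log-odds 0
        object.__setattr__(self, "frequencies", freq)
        object.__setattr__(self, "background", bg)
        object.__setattr__(self, "_log_odds", lo)

    @property
    def width(self) -> int:
        return self.frequencies.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(AA_ALPHABET[i] for i in self.frequencies.argmax(axis=1))

    @property
    def consensus_score(self) -> float:
        """Log-odds score of the profile's own consensus sequence."""
        return float(self._log_odds[:, :20].max(axis=1).sum())

    def window_scores(self, encoded: np.ndarray) -> np.ndarray:
        """Score every placement of this profile along an encoded sequence."""
        n = encoded.size - self.width + 1
        if n <= 0:
            return np.empty(0)
        scores = np.zeros(n)
        # accumulate right-to-left so sums associate identically to the
        # placement DP (and its brute-force oracle)
        for offset in range(self.width - 1, -1, -1):
            scores += self._log_odds[offset, encoded[offset : offset + n]]
        return scores

    def score_fragment(self, fragment: str) -> float:
        if len(fragment) != self.width:
            raise DetectionError(f"fragment length {len(fragment)} != profile width {self.width}")
        return float(self.window_scores(encode_sequence(fragment))[0])


@dataclass(frozen=True)
class ProfileSet:
    """Five CSR profiles trained from one collection of fingerprints."""

    name: str
    profiles: tuple[CSRProfile, ...]
    schema: FingerprintSchema = field(default_factory=default_schema)

    def __post_init__(self) -> None:
        if len(self.profiles) != 5:
            raise DetectionError("a profile set holds exactly five CSR profiles")
        for prof, width in zip(self.profiles, self.schema.widths):
            if prof.width != width:
                raise DetectionError(
                    f"CSR-{prof.csr_index} profile width {prof.width} != schema width {width}"
                )

    def score_fingerprint(self, fingerprint: str) -> float:
        """Total log-odds of an extracted 36-mer under this set."""
        if len(fingerprint) != FINGERPRINT_LENGTH:
            raise DetectionError("fingerprint must have length 36")
        total = 0.0
        offset = 0
        for prof in self.profiles:
            total += prof.score_fragment(fingerprint[offset : offset + prof.width])
            offset += prof.width
        return total

    def floors(self, floor_fraction: float) -> tuple[float, ...]:
        return tuple(floor_fraction * p.consensus_score for p in self.profiles)

    def to_jsonable(self) -> dict:
        return {
            "name": self.name,
            "pseudocount": self.profiles[0].pseudocount,
            "background": list(self.profiles[0].background),
            "csr_frequencies": [p.frequencies.tolist() for p in self.profiles],
        }

    @classmethod
    def from_jsonable(cls, doc: Mapping, schema: FingerprintSchema | None = None) -> "ProfileSet":
        schema = schema or default_schema()
        bg = np.asarray(doc["background"], dtype=float)
        profiles = tuple(
            CSRProfile(
                csr_index=k + 1,
                frequencies=np.asarray(freq, dtype=float),
                pseudocount=float(doc["pseudocount"]),
                background=bg,
            )
            for k, freq in enumerate(doc["csr_frequencies"])
        )
        return cls(name=str(doc["name"]), profiles=profiles, schema=schema)


def profiles_from_alignment(
    fingerprints: Iterable[str],
    pseudocount: float = 0.5,
    *,
    schema: FingerprintSchema | None = None,
    background: Sequence[float] | None = None,
    name: str = "pooled",
) -> ProfileSet:
    """Train the five CSR profiles from aligned 36-position fingerprints.

    Per-column frequencies are ``(count + pseudocount) / (n + 20 * pseudocount)``
    where ``n`` counts the standard residues observed in that column;
    non-standard residues contribute no counts.
    """
    schema = schema or default_schema()
    fps = list(fingerprints)
    if not fps:
        raise DetectionError("cannot train profiles from an empty fingerprint set")
    if pseudocount <= 0:
        raise DetectionError("pseudocount must be > 0")
    for fp in fps:
        if len(fp) != FINGERPRINT_LENGTH:
            raise DetectionError(f"all fingerprints must have length 36, got {len(fp)}")
    bg = np.full(20, 1 / 20) if background is None else np.asarray(background, dtype=float)
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0) or bg.min() <= 0:
        raise DetectionError("background must be 20 positive probabilities summing to 1")

    encoded = np.array([encode_sequence(fp) for fp in fps])  # (n, 36)
    counts = np.zeros((FINGERPRINT_LENGTH, 20))
    for col in range(FINGERPRINT_LENGTH):
        column = encoded[:, col]
        std = column[column < _UNKNOWN]
        counts[col] = np.bincount(std, minlength=20)
    n_std = counts.sum(axis=1, keepdims=True)
    freq = (counts + pseudocount) / (n_std + 20 * pseudocount)

    profiles = []
    for k, (start, end) in enumerate(schema.csr_spans, start=1):
        profiles.append(
            CSRProfile(
                csr_index=k,
                frequencies=freq[start - 1 : end],
                pseudocount=pseudocount,
                background=bg,
            )
        )
    return ProfileSet(name=name, profiles=tuple(profiles), schema=schema)


def save_profile_sets(path, sets: Sequence[ProfileSet], **extra) -> None:
    doc = {"format_version": 1, **extra, "profile_sets": [s.to_jsonable() for s in sets]}
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_profile_sets(path, schema: FingerprintSchema | None = None) -> list[ProfileSet]:
    with open(path) as fh:
        doc = json.load(fh)
    return [ProfileSet.from_jsonable(d, schema) for d in doc["profile_sets"]]


@dataclass(frozen=True)
class CSRHits:
    """Placement of the five CSR windows in one sequence, or an elimination."""

    ranges: tuple[tuple[int, int], ...] | None  # 1-based inclusive
    csr_scores: tuple[float, ...] | None
    total_score: float | None
    eliminated: bool
    missing_csrs: tuple[int, ...] = ()
    reason: str | None = None
    profile_name: str | None = None

    @property
    def accepted(self) -> bool:
        return not self.eliminated


def _suffix_argmax(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Suffix running maximum and the *earliest* index attaining it."""
    rev_max = np.maximum.accumulate(values[::-1])[::-1]
    idx = np.arange(values.size)
    hit = np.where(values == rev_max, idx, values.size)
    earliest = np.minimum.accumulate(hit[::-1])[::-1]
    return rev_max, earliest


def _best_placement(
    window_scores: list[np.ndarray], widths: Sequence[int], min_spacer: int
) -> tuple[tuple[int, ...], tuple[float, ...], float] | None:
    """Exact DP over ordered non-overlapping placements of the five windows.

    Returns 0-based starts, per-CSR scores and the total; ``None`` when the
    sequence is too short for any valid placement.  Among score ties the
    lexicographically smallest start tuple is chosen.
    """
    n_csr = len(window_scores)
    gaps = [widths[k] + min_spacer for k in range(n_csr - 1)]
    # B[k][p]: best total of CSRs k..4 with CSR k starting at p
    B: list[np.ndarray] = [np.empty(0)] * n_csr
    B[-1] = window_scores[-1]
    if B[-1].size == 0:
        return None
    suffix: list[tuple[np.ndarray, np.ndarray]] = [None] * n_csr  # type: ignore[list-item]
    suffix[-1] = _suffix_argmax(B[-1])
    for k in range(n_csr - 2, -1, -1):
        nxt_max, _ = suffix[k + 1]
        limit = B[k + 1].size - gaps[k]  # CSR k may start at p iff p < limit
        if limit <= 0 or window_scores[k].size == 0:
            return None
        usable = min(limit, window_scores[k].size)
        B[k] = window_scores[k][:usable] + nxt_max[gaps[k] : gaps[k] + usable]
        suffix[k] = _suffix_argmax(B[k])

    starts: list[int] = []
    cursor = 0
    for k in range(n_csr):
        _, earliest = suffix[k]
        if cursor >= B[k].size:
            return None  # pragma: no cover - guarded by limit checks above
        p = int(earliest[cursor])
        starts.append(p)
        if k < n_csr - 1:
            cursor = p + gaps[k]
    scores = tuple(float(window_scores[k][starts[k]]) for k in range(n_csr))
    total = float(B[0][starts[0]])
    return tuple(starts), scores, total


def locate_csrs(
    sequence: str,
    profiles: ProfileSet,
    schema: FingerprintSchema | None = None,
    min_spacer: int = 5,
    score_floor: Sequence[float] | None = None,
    floor_fraction: float = 0.15,
) -> CSRHits:
    """Place the five CSR windows in ``sequence`` and apply the elimination rule.

    ``score_floor`` gives five absolute per-CSR floors; by default each floor
    is ``floor_fraction`` of the corresponding profile's consensus score.
    """
    schema = schema or profiles.schema
    widths = schema.widths
    floors = tuple(score_floor) if score_floor is not None else profiles.floors(floor_fraction)
    if len(floors) != 5:
        raise DetectionError("score_floor must provide one floor per CSR")

    min_len = FINGERPRINT_LENGTH + 4 * min_spacer
    if len(sequence) < min_len:
        return CSRHits(
            ranges=None, csr_scores=None, total_score=None, eliminated=True,
            missing_csrs=(1, 2, 3, 4, 5),
            reason=f"too short ({len(sequence)} < {min_len})",
            profile_name=profiles.name,
        )

    encoded = encode_sequence(sequence)
    window_scores = [prof.window_scores(encoded) for prof in profiles.profiles]
    placement = _best_placement(window_scores, widths, min_spacer)
    if placement is None:  # pragma: no cover - length guard above
        return CSRHits(
            ranges=None, csr_scores=None, total_score=None, eliminated=True,
            missing_csrs=(1, 2, 3, 4, 5), reason="no valid placement",
            profile_name=profiles.name,
        )
    starts, scores, total = placement
    ranges = tuple((s + 1, s + w) for s, w in zip(starts, widths))
    missing = tuple(k + 1 for k in range(5) if scores[k] < floors[k])
    if missing:
        return CSRHits(
            ranges=ranges, csr_scores=scores, total_score=total, eliminated=True,
            missing_csrs=missing,
            reason="below score floor: CSR-" + ",".join(str(m) for m in missing),
            profile_name=profiles.name,
        )
    return CSRHits(
        ranges=ranges, csr_scores=scores, total_score=total, eliminated=False,
        profile_name=profiles.name,
    )


def extract_fingerprint(sequence: str, hits: CSRHits) -> str:
    """Concatenate the five CSR subsequences (CSR-1..CSR-5) into the 36-mer."""
    if hits.eliminated or hits.ranges is None:
        raise DetectionError("cannot extract a fingerprint from an eliminated sequence")
    fp = "".join(sequence[s - 1 : e] for s, e in hits.ranges)
    if len(fp) != FINGERPRINT_LENGTH:  # pragma: no cover - guarded by CSRHits construction
        raise DetectionError(f"extracted fingerprint has length {len(fp)}")
    return fp


def scan_sequence(
    sequence: str,
    profile_sets: Sequence[ProfileSet],
    schema: FingerprintSchema | None = None,
    min_spacer: int = 5,
    floor_fraction: float = 0.15,
) -> CSRHits:
    """Locate CSRs using several profile sets; the best one decides.

    Every set places its five windows; the set with the highest total
    log-odds wins, and that set's floor test alone decides acceptance or
    elimination.  A spurious window that only clears the floor of some
    poorly matching profile set therefore cannot rescue a sequence.
    """
    if not profile_sets:
        raise DetectionError("at least one profile set is required")
    best: CSRHits | None = None
    for pset in profile_sets:
        hits = locate_csrs(
            sequence, pset, schema=schema, min_spacer=min_spacer, floor_fraction=floor_fraction
        )
        score = hits.total_score if hits.total_score is not None else -np.inf
        if best is None or score > (best.total_score if best.total_score is not None else -np.inf):
            best = hits
    assert best is not None
    return best
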