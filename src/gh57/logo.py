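"""Numerical sequence-logo matrices for 36-position CSR fingerprints.

A logo over a set of fingerprints is the per-position residue frequency
matrix together with the Shannon information content of each column,

    IC = log2(20) + sum_a p_a * log2(p_a),   with 0 * log2(0) := 0,

in bits: 0 for a uniform column, log2(20) ~ 4.3219 for an invariant one.
No small-sample correction is applied (display logos conventionally subtract
one; it is omitted here so the values have an exact closed form), and no
pseudocount is added: the matrix reports observed frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .schema import AA_ALPHABET, AA_INDEX, FINGERPRINT_LENGTH, FingerprintSchema, default_schema

MAX_IC_BITS = float(np.log2(20))


def information_content(frequencies) -> float | np.ndarray:
    """Shannon information content in bits of one or many residue columns.

    Accepts a single length-20 frequency vector (returns a float) or a
    ``(positions, 20)`` matrix (returns one value per row).  Frequencies must
    be non-negative and sum to 1 per column.
    """
    freq = np.asarray(frequencies, dtype=float)
    single = freq.ndim == 1
    freq = np.atleast_2d(freq)
    if freq.shape[1] != 20:
        raise ValueError("expected frequencies over the 20-residue alphabet")
    if freq.min() < 0:
        raise ValueError("frequencies must be non-negative")
    if not np.allclose(freq.sum(axis=1), 1.0):
        raise ValueError("frequencies must sum to 1 per position")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq > 0, freq * np.log2(np.where(freq > 0, freq, 1.0)), 0.0)
    ic = MAX_IC_BITS + plogp.sum(axis=1)
    ic = np.clip(ic, 0.0, MAX_IC_BITS)
    return float(ic[0]) if single else ic


@dataclass(frozen=True)
class LogoMatrix:
    """Frequencies and per-position information content for one group's logo."""

    group: str
    n: int
    frequencies: np.ndarray  # (36, 20)
    information: np.ndarray  # (36,)
    schema: FingerprintSchema

    def modal_residue(self, pos: int) -> str:
        """Most frequent residue at a 1-based fingerprint position."""
        return AA_ALPHABET[int(self.frequencies[pos - 1].argmax())]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.frequencies, columns=list(AA_ALPHABET))
        df.insert(0, "position", np.arange(1, FINGERPRINT_LENGTH + 1))
        df.insert(1, "csr", [self.schema.position_to_csr(p)[0] for p in df["position"]])
        df["information_bits"] = self.information
        return df

    def to_jsonable(self) -> dict:
        return {
            "group": self.group,
            "n": self.n,
            "alphabet": AA_ALPHABET,
            "csr_spans": [list(s) for s in self.schema.csr_spans],
            "frequencies": self.frequencies.tolist(),
            "information_bits": self.information.tolist(),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_jsonable())


def logo_from_fingerprints(
    fingerprints: Iterable[str],
    group: str = "",
    schema: FingerprintSchema | None = None,
) -> LogoMatrix:
    """Count-based logo matrix of a set of 36-position fingerprints.

    Non-standard residues are ignored in the counts; a column consisting only
    of non-standard residues is rejected.
    """
    schema = schema or default_schema()
    fps = list(fingerprints)
    if not fps:
        raise ValueError("cannot build a logo from an empty fingerprint set")
    for fp in fps:
        if len(fp) != FINGERPRINT_LENGTH:
            raise ValueError(f"all fingerprints must have length 36, got {len(fp)}")
    counts = np.zeros((FINGERPRINT_LENGTH, 20))
    for fp in fps:
        for col, ch in enumerate(fp.upper()):
            idx = AA_INDEX.get(ch)
            if idx is not None:
                counts[col, idx] += 1
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = int(np.argmax(totals == 0)) + 1
        raise ValueError(f"position {bad} has no standard residues")
    freq = counts / totals[:, None]
    return LogoMatrix(
        group=group,
        n=len(fps),
        frequencies=freq,
        information=np.asarray(information_content(freq)),
        schema=schema,
    )
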