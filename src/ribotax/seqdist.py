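"""Pairwise distances between aligned nucleotide sequences.

Supports the uncorrected p distance, the Jukes-Cantor (JC69) correction
d = -(3/4) ln(1 - 4p/3), and the Kimura two-parameter (K80) correction
d = -(1/2) ln((1 - 2P - Q) sqrt(1 - 2Q)) with P/Q the transition and
transversion proportions. Columns with a gap or N in either sequence of a
pair are excluded pairwise.
"""

from __future__ import annotations

import numpy as np
from skbio import DistanceMatrix

MODELS = ("p", "JC69", "K80")

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4, "-": 5}
#: purine/pyrimidine class per code (A,G -> 0; C,T -> 1); 2 = not comparable
_PUR_PYR = np.array([0, 1, 0, 1, 2, 2], dtype=np.int8)


def encode_alignment(sequences: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Encode equal-length aligned sequences into an integer matrix."""
    labels = list(sequences)
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    mat = np.empty((len(labels), lengths.pop()), dtype=np.int8)
    for i, lab in enumerate(labels):
        try:
            mat[i] = [_CODE[c] for c in sequences[lab]]
        except KeyError as exc:
            raise ValueError(f"sequence {lab!r}: invalid character {exc}") from exc
    return labels, mat


def pairwise_distance(sequences: dict[str, str], model: str = "p") -> DistanceMatrix:
    """Distance matrix between aligned sequences under ``model``.

    Raises if a pair has no comparable columns, or if a correction is
    undefined for a pair (saturation: log argument <= 0).
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODELS}")
    labels, mat = encode_alignment(sequences)
    n = len(labels)
    comparable = mat < 4  # A/C/G/T only
    klass = _PUR_PYR[mat]
    out = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            ok = comparable[i] & comparable[j]
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"pair ({labels[i]!r}, {labels[j]!r}) has zero comparable columns"
                )
            diff = (mat[i] != mat[j]) & ok
            p = float(diff.sum()) / m
            if model == "p":
                d = p
            elif model == "JC69":
                arg = 1.0 - 4.0 * p / 3.0
                if arg <= 0.0:
                    raise ValueError(
                        f"JC69 undefined (saturated) for pair ({labels[i]!r}, {labels[j]!r})"
                    )
                d = -0.75 * np.log(arg)
            else:  # K80
                transitions = diff & (klass[i] == klass[j])
                P = float(transitions.sum()) / m
                Q = p - P
                arg1 = 1.0 - 2.0 * P - Q
                arg2 = 1.0 - 2.0 * Q
                if arg1 <= 0.0 or arg2 <= 0.0:
                    raise ValueError(
                        f"K80 undefined (saturated) for pair ({labels[i]!r}, {labels[j]!r})"
                    )
                d = -0.5 * np.log(arg1 * np.sqrt(arg2))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, labels)


def pairwise_identity(a: str, b: str) -> float:
    """Ungapped pairwise identity over aligned columns (gap/N excluded)."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    aa = np.frombuffer(a.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.encode(), dtype=np.uint8)
    bad = np.frombuffer(b"N-", dtype=np.uint8)
    ok = ~(np.isin(aa, bad) | np.isin(bb, bad))
    m = int(ok.sum())
    if m == 0:
        return 0.0
    return float(((aa == bb) & ok).sum()) / m
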