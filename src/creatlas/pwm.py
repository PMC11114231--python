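"""Position weight matrices and catalog parsers (MEME-minimal, JASPAR PFM)."""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

__all__ = ["PWM", "read_meme_minimal", "write_meme_minimal", "read_jaspar_pfm"]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.upper().translate(_COMPLEMENT)[::-1]


def encode_sequence(seq: str) -> np.ndarray:
    """A/C/G/T -> 0..3; any other symbol (incl. N) -> 4."""
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int64)


@dataclass(frozen=True)
class PWM:
    """L x 4 per-position nucleotide probabilities (A, C, G, T order)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError("PWM must be an L x 4 matrix with L >= 1")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be >= 0")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("PWM columns must each sum to 1 (tolerance 1e-6)")
        object.__setattr__(self, "matrix", m)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.matrix.argmax(axis=1))

    def reverse_complement(self) -> "PWM":
        return PWM(self.matrix[::-1, ::-1])

    @classmethod
    def from_counts(cls, counts: np.ndarray, pseudo: float = 0.0) -> "PWM":
        c = np.asarray(counts, dtype=np.float64) + pseudo
        return cls(c / c.sum(axis=1, keepdims=True))


def read_meme_minimal(path) -> dict[str, PWM]:
    """Parse a MEME-minimal-format motif file into a catalog."""
    catalog: dict[str, PWM] = {}
    name: str | None = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("MOTIF"):
                parts = line.split()
                name = parts[1]
                rows, expecting = [], 0
            elif line.startswith("letter-probability matrix"):
                m = re.search(r"w=\s*(\d+)", line)
                expecting = int(m.group(1)) if m else -1
            elif name is not None and expecting != 0 and line and line[0] in "0123456789.":
                rows.append([float(x) for x in line.split()])
                if len(rows) == expecting:
                    catalog[name] = PWM(np.array(rows))
                    name, rows, expecting = None, [], 0
    if name is not None and rows:
        catalog[name] = PWM(np.array(rows))
    return catalog


def write_meme_minimal(catalog: dict[str, PWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for name, pwm in catalog.items():
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def read_jaspar_pfm(path) -> dict[str, PWM]:
    """Parse JASPAR-style PFM text (>ID header, 4 count rows A/C/G/T)."""
    catalog: dict[str, PWM] = {}
    name: str | None = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None and len(rows) == 4:
                    catalog[name] = PWM.from_counts(np.array(rows).T)
                name = line[1:].split()[0]
                rows = []
            else:
                nums = re.findall(r"[\d.]+", line.split("[")[-1].split("]")[0])
                rows.append([float(x) for x in nums])
    if name is not None and len(rows) == 4:
        catalog[name] = PWM.from_counts(np.array(rows).T)
    return catalog
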