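"""TF motif models: position weight matrices, consensus, JASPAR/MEME parsing."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["MotifModel", "read_motifs", "write_meme"]

_BASES = "ACGT"


@dataclass
class MotifModel:
    """A named motif as a 4 x width column-stochastic PWM (rows A,C,G,T)."""

    name: str
    pwm: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=np.float64)
        if self.pwm.ndim != 2 or self.pwm.shape[0] != 4:
            raise ValueError(
                f"motif {self.name!r}: PWM must be 4 x width, "
                f"got shape {self.pwm.shape}"
            )
        sums = self.pwm.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(
                f"motif {self.name!r}: PWM columns must sum to 1 "
                f"(max deviation {np.abs(sums - 1).max():.3g})"
            )

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    def consensus(self) -> str:
        """Max-probability base per column; ties resolved in A<C<G<T order."""
        return "".join(_BASES[i] for i in self.pwm.argmax(axis=0))


def _normalize_counts(name: str, counts: np.ndarray, source: str) -> MotifModel:
    counts = np.asarray(counts, dtype=np.float64)
    sums = counts.sum(axis=0)
    if (sums <= 0).any():
        raise ValueError(f"motif {name!r}: column sums to 0, cannot normalize")
    return MotifModel(name, counts / sums, source)


def _parse_jaspar(lines: list[str], source: str) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    name, rows = None, []
    for ln in lines + [">"]:
        if ln.startswith(">"):
            if name is not None:
                if len(rows) != 4:
                    raise ValueError(
                        f"motif {name!r}: expected 4 base rows, got {len(rows)}"
                    )
                motifs.append(_normalize_counts(name, np.array(rows), source))
            name = ln[1:].strip().split()[0] if len(ln) > 1 else None
            rows = []
        elif ln.strip():
            body = ln.replace("[", " ").replace("]", " ")
            fields = body.split()
            if fields and fields[0].upper() in ("A", "C", "G", "T"):
                fields = fields[1:]
            rows.append([float(x) for x in fields])
    return motifs


def _parse_meme(lines: list[str], source: str) -> list[MotifModel]:
    motifs: list[MotifModel] = []
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("MOTIF"):
            name = ln.split()[1]
            while i < len(lines) and not lines[i].startswith(
                "letter-probability matrix"
            ):
                i += 1
            if i == len(lines):
                raise ValueError(f"motif {name!r}: no probability matrix")
            i += 1
            rows = []
            while i < len(lines):
                fields = lines[i].split()
                if len(fields) != 4:
                    break
                try:
                    rows.append([float(x) for x in fields])
                except ValueError:
                    break
                i += 1
            if not rows:
                raise ValueError(f"motif {name!r}: empty probability matrix")
            motifs.append(
                _normalize_counts(name, np.array(rows).T, source)
            )
        else:
            i += 1
    return motifs


def read_motifs(path: str | Path, fmt: str | None = None) -> list[MotifModel]:
    """Read motifs from a JASPAR pfm or MEME minimal file.

    Counts (JASPAR) or probabilities (MEME) are normalized column-wise with no
    pseudocount. ``fmt`` is auto-detected from content when omitted.
    """
    text = Path(path).read_text()
    lines = [ln.rstrip() for ln in text.splitlines() if ln.strip()]
    if fmt is None:
        fmt = "meme" if any(ln.startswith("MEME version") or
                            ln.startswith("MOTIF") for ln in lines) else "jaspar"
    if fmt == "jaspar":
        motifs = _parse_jaspar(lines, str(path))
    elif fmt == "meme":
        motifs = _parse_meme(lines, str(path))
    else:
        raise ValueError(f"unknown motif format {fmt!r}")
    if not motifs:
        raise ValueError(f"no motifs parsed from {path}")
    return motifs


def write_meme(motifs: list[MotifModel], path: str | Path) -> None:
    """Write motifs in MEME minimal format."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write(
            "Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= 20 E= 0\n"
            )
            for col in m.pwm.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")
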