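"""Readers, writers and fixture generation.

Formats: FASTA input (via Biopython), whitespace-delimited score matrix
files in the NCBI style ('#' comments, a header line of alphabet letters,
then one row per letter), flat key-value parameter files, and MAF/TSV
alignment output with per-column reliability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
from Bio import SeqIO

from .core import (
    DNA,
    Alphabet,
    AlnprobError,
    LetterProbs,
    PairProbs,
    PhmmParams,
    PrimedParams,
)
from .dp import LocalAlignment, Sequence
from .matrices import BUILTIN_MATRICES

__all__ = [
    "MatrixFile",
    "parse_fasta",
    "parse_matrix",
    "write_matrix",
    "write_params",
    "read_params",
    "write_primed",
    "read_primed",
    "write_posterior_maf",
    "write_posterior_tsv",
    "reliability_char",
    "make_fixture",
]


@dataclass
class MatrixFile:
    """A parsed score matrix plus where it came from."""

    alphabet: Alphabet
    S: np.ndarray
    source: str


def parse_fasta(path: str | Path, alphabet: Alphabet = DNA) -> list[Sequence]:
    """Read FASTA records, case-folding letters to upper.

    Errors on an empty file, duplicate IDs, or letters outside the alphabet
    (the error names the record and position).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlnprobError(f"no FASTA records in {path}")
    seen: set[str] = set()
    out: list[Sequence] = []
    allowed = set(alphabet.letters)
    for rec in records:
        if rec.id in seen:
            raise AlnprobError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        letters = str(rec.seq).upper()
        for pos, c in enumerate(letters):
            if c not in allowed:
                raise AlnprobError(
                    f"record {rec.id!r}: illegal character {c!r} at "
                    f"position {pos}"
                )
        out.append(Sequence(rec.id, letters))
    return out


def parse_matrix(source: str | Path) -> MatrixFile:
    """Parse a score matrix file, or fetch a builtin by name.

    Builtins: "HoxD70" (inter-species genome alignment matrix) and "Simple"
    (+1/-1).  File format: '#' comments; first non-comment line lists the
    alphabet letters; each following line is "letter score score ...".
    """
    if isinstance(source, str) and source in BUILTIN_MATRICES:
        return MatrixFile(DNA, BUILTIN_MATRICES[source].copy(), source)
    path = Path(source)
    lines = [
        ln
        for ln in path.read_text().splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise AlnprobError(f"no matrix content in {path}")
    header = lines[0].split()
    if len(set(header)) != len(header):
        raise AlnprobError(f"duplicate letters in matrix header of {path}")
    k = len(header)
    if len(lines) - 1 != k:
        raise AlnprobError(
            f"{path}: expected {k} matrix rows, found {len(lines) - 1}"
        )
    alphabet = Alphabet(tuple(c.upper() for c in header))
    S = np.zeros((k, k))
    seen_rows: set[str] = set()
    for ln in lines[1:]:
        parts = ln.split()
        if len(parts) != k + 1:
            raise AlnprobError(
                f"{path}: ragged row {ln!r} (expected letter + {k} scores)"
            )
        letter = parts[0].upper()
        if letter in seen_rows:
            raise AlnprobError(f"{path}: duplicate row letter {letter!r}")
        seen_rows.add(letter)
        i = alphabet.index(letter)
        for j, cell in enumerate(parts[1:]):
            try:
                S[i, j] = float(cell)
            except ValueError:
                raise AlnprobError(
                    f"{path}: non-numeric cell {cell!r} in row {letter!r}"
                ) from None
    return MatrixFile(alphabet, S, str(path))


def write_matrix(mf: MatrixFile, path: str | Path) -> None:
    """Write a matrix file that parses back to exactly the same values."""
    lines = ["# score matrix written by alnprob"]
    lines.append(" ".join(mf.alphabet.letters))
    for i, letter in enumerate(mf.alphabet.letters):
        cells = " ".join(_fmt(v) for v in mf.S[i])
        lines.append(f"{letter} {cells}")
    Path(path).write_text("\n".join(lines) + "\n")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


# ---------------------------------------------------------------------------
# parameter files: flat "name value" lines


def write_params(params: PhmmParams, path: str | Path) -> None:
    lines = [f"topology {params.topology}"]
    letters = params.phi.alphabet.letters
    lines.append("alphabet " + "".join(letters))
    for name in ("omega_D", "omega_I", "gamma", "alpha_D", "beta_D",
                 "alpha_I", "beta_I"):
        v = getattr(params, name)
        if v is not None:
            lines.append(f"{name} {_fmt(v)}")
    for x, p in zip(letters, params.phi.p):
        lines.append(f"phi_{x} {_fmt(p)}")
    for y, p in zip(letters, params.psi.p):
        lines.append(f"psi_{y} {_fmt(p)}")
    for i, x in enumerate(letters):
        for j, y in enumerate(letters):
            lines.append(f"pi_{x}{y} {_fmt(params.pi.pi[i, j])}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_kv(path: str | Path) -> dict[str, str]:
    kv: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise AlnprobError(f"bad parameter line {ln!r}")
        kv[parts[0]] = parts[1]
    return kv


def read_params(path: str | Path) -> PhmmParams:
    kv = _read_kv(path)
    topology = kv["topology"]
    if topology not in ("gapless", "linear", "A", "B"):
        raise AlnprobError(f"unknown topology {topology!r}")
    alphabet = Alphabet(tuple(kv["alphabet"]))
    letters = alphabet.letters
    phi = LetterProbs(alphabet, [float(kv[f"phi_{x}"]) for x in letters])
    psi = LetterProbs(alphabet, [float(kv[f"psi_{y}"]) for y in letters])
    pi = PairProbs(
        alphabet,
        [[float(kv[f"pi_{x}{y}"]) for y in letters] for x in letters],
    )
    opt = lambda k: float(kv[k]) if k in kv else None  # noqa: E731
    return PhmmParams(
        topology, phi, psi, pi,
        omega_D=float(kv["omega_D"]), omega_I=float(kv["omega_I"]),
        gamma=float(kv["gamma"]),
        alpha_D=opt("alpha_D"), beta_D=opt("beta_D"),
        alpha_I=opt("alpha_I"), beta_I=opt("beta_I"),
    )


def write_primed(primed: PrimedParams, path: str | Path) -> None:
    letters = primed.alphabet.letters
    lines = ["topology A", "alphabet " + "".join(letters)]
    for name in ("c_pr", "a_D_pr", "b_D_pr", "a_I_pr", "b_I_pr"):
        lines.append(f"{name} {_fmt(getattr(primed, name))}")
    for i, x in enumerate(letters):
        for j, y in enumerate(letters):
            lines.append(f"Sprime_{x}{y} {_fmt(primed.Sprime[i, j])}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_primed(path: str | Path) -> PrimedParams:
    kv = _read_kv(path)
    alphabet = Alphabet(tuple(kv["alphabet"]))
    letters = alphabet.letters
    Sp = np.array(
        [[float(kv[f"Sprime_{x}{y}"]) for y in letters] for x in letters]
    )
    return PrimedParams(
        alphabet, Sp, float(kv["c_pr"]),
        a_D_pr=float(kv["a_D_pr"]), b_D_pr=float(kv["b_D_pr"]),
        a_I_pr=float(kv["a_I_pr"]), b_I_pr=float(kv["b_I_pr"]),
    )


# ---------------------------------------------------------------------------
# alignment output


def reliability_char(p: float) -> str:
    """One-character encoding of a column reliability.

    '0'-'9' are the deciles floor(p*10); probabilities >= 0.95 get '+' (the
    top bin), so a fully reliable column reads '+'.
    """
    if p >= 0.95:
        return "+"
    return str(max(0, min(9, int(p * 10.0))))


def write_posterior_maf(
    aln: LocalAlignment,
    reliabilities: list[float] | None,
    r_id: str,
    q_id: str,
    r_size: int | None = None,
    q_size: int | None = None,
) -> str:
    """Render one alignment as a MAF block with an optional probability line.

    The 'p' line encodes per-column reliability via :func:`reliability_char`.
    An empty alignment yields no block (empty string).
    """
    if not aln.columns:
        return ""
    if reliabilities is not None and len(reliabilities) != len(aln.columns):
        raise AlnprobError("reliability list length does not match columns")
    r_text = "".join(c[1] if c[0] in ("M", "D") else "-" for c in aln.columns)
    q_text = "".join(
        c[2] if c[0] == "M" else (c[1] if c[0] == "I" else "-")
        for c in aln.columns
    )
    r_size = aln.r_end if r_size is None else r_size
    q_size = aln.q_end if q_size is None else q_size
    width = max(len(r_id), len(q_id))
    lines = [f"a score={aln.score:g}"]
    lines.append(
        f"s {r_id:<{width}} {aln.r_start} {aln.r_end - aln.r_start} + "
        f"{r_size} {r_text}"
    )
    lines.append(
        f"s {q_id:<{width}} {aln.q_start} {aln.q_end - aln.q_start} + "
        f"{q_size} {q_text}"
    )
    if reliabilities is not None:
        lines.append(
            f"p {' ' * width} " + "".join(
                reliability_char(p) for p in reliabilities
            )
        )
    return "\n".join(lines) + "\n\n"


def write_posterior_tsv(
    aln: LocalAlignment, reliabilities: list[float]
) -> str:
    """Full-precision TSV: column index, op, letters, reliability."""
    lines = ["column\top\tref\tquery\treliability"]
    i, j = aln.r_start, aln.q_start
    for k, (col, p) in enumerate(zip(aln.columns, reliabilities)):
        if col[0] == "M":
            lines.append(f"{k}\tM\t{col[1]}\t{col[2]}\t{p!r}")
            i += 1
            j += 1
        elif col[0] == "D":
            lines.append(f"{k}\tD\t{col[1]}\t-\t{p!r}")
            i += 1
        else:
            lines.append(f"{k}\tI\t-\t{col[1]}\t{p!r}")
            j += 1
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# synthetic fixtures


def make_fixture(
    kind: str,
    length: int,
    divergence: float = 0.0,
    seed: int = 0,
    alphabet: Alphabet = DNA,
) -> tuple[Sequence, Sequence]:
    """Seeded generator of sequence pairs with controlled structure.

    kinds: "identity" (R == Q), "diverged" (independent substitutions at the
    given rate, no indels), "repeat" (Q carries a tandem duplication of R's
    middle third), "random" (independent uniform sequences).
    """
    if not 0.0 <= divergence <= 1.0:
        raise AlnprobError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, length]))
    letters = np.array(list(alphabet.letters))
    k = len(letters)
    base = rng.integers(0, k, size=length)
    r = "".join(letters[base])
    if kind == "identity":
        return Sequence("ref", r), Sequence("query", r)
    if kind == "diverged":
        hit = rng.random(length) < divergence
        shift = rng.integers(1, k, size=length)
        q_idx = np.where(hit, (base + shift) % k, base)
        return Sequence("ref", r), Sequence("query", "".join(letters[q_idx]))
    if kind == "repeat":
        third = max(1, length // 3)
        mid = r[third : 2 * third]
        q = r[: 2 * third] + mid + r[2 * third :]
        return Sequence("ref", r), Sequence("query", q)
    if kind == "random":
        other = rng.integers(0, k, size=length)
        return Sequence("ref", r), Sequence("query", "".join(letters[other]))
    raise AlnprobError(f"unknown fixture kind {kind!r}")
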