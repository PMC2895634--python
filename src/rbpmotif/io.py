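"""Plain-text readers and writers.

All formats are diff-able text: tab-separated tables with a header row and
6-decimal floats, FASTA for sequences, a line-oriented annotation-profile
format, a key-value motif-model format (10 significant digits), and
one-structure-per-line dot-bracket sample files.  Readers validate and report
the offending line number.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .alphabet import AnnotationAlphabet, plum_alphabet, single_letter_alphabet
from .model import AffinityMap, MotifModel
from .records import RnaRecord
from .structure import AnnotationProfile, InvalidSequenceError, encode

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file failed validation; the message carries the line number."""


def _check_seq(seq: str, path, lineno: int) -> str:
    s = seq.upper().replace("T", "U")
    for ch in s:
        if ch not in "ACGUN":
            raise FormatError(
                f"{path}:{lineno}: illegal sequence character {ch!r}"
            )
    return s


def read_affinity_table(path) -> list[RnaRecord]:
    """Read tab-delimited records: affinity, sequence[, id[, group]].

    T is silently mapped to U (warned once per file); any other non-ACGUN
    character is an error naming the line.
    """
    path = Path(path)
    records = []
    saw_t = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: expected >= 2 tab-separated fields")
            try:
                affinity = float(parts[0])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: malformed affinity value {parts[0]!r}"
                ) from None
            raw_seq = parts[1].strip()
            if not raw_seq:
                raise FormatError(f"{path}:{lineno}: empty sequence")
            if "T" in raw_seq.upper():
                saw_t = True
            seq = _check_seq(raw_seq, path, lineno)
            rec_id = parts[2] if len(parts) > 2 and parts[2] else f"rec{lineno}"
            group = parts[3] if len(parts) > 3 and parts[3] else None
            records.append(RnaRecord(id=rec_id, seq=seq, affinity=affinity, group=group))
    if saw_t:
        logger.warning("%s: T bases mapped to U", path)
    return records


def write_affinity_table(path, records: Sequence[RnaRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fields = [f"{r.affinity:.6f}", r.seq, r.id]
            if r.group is not None:
                fields.append(r.group)
            fh.write("\t".join(fields) + "\n")


def read_fasta(path) -> list[RnaRecord]:
    """Read sequences from FASTA (T mapped to U)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace("T", "U")
        try:
            encode(seq.replace("N", "A"))
        except InvalidSequenceError as exc:
            raise FormatError(f"{path}: record {rec.id}: {exc}") from exc
        out.append(RnaRecord(id=rec.id, seq=seq))
    return out


def write_fasta(path, records: Sequence[RnaRecord]) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r.id}\n{r.seq}\n")


# ---------------------------------------------------------------------------
# annotation-profile files
# ---------------------------------------------------------------------------

def write_profiles(path, records: Sequence[RnaRecord]) -> None:
    """Write per-record annotation profiles.

    Format: a header line ``#alphabet <letters>``; then per record one ``>id``
    line followed by one line per letter: the letter, a tab, and the per-base
    probabilities to 6 decimals, tab-separated.
    """
    recs = [r for r in records if r.profile is not None]
    if not recs:
        raise ValueError("no records carry profiles")
    alphabet = recs[0].profile.alphabet
    with open(path, "w") as fh:
        fh.write(f"#alphabet {alphabet.name}\n")
        for r in recs:
            fh.write(f">{r.id}\n")
            for ai, letter in enumerate(alphabet.letters):
                row = "\t".join(f"{v:.6f}" for v in r.profile.values[ai])
                fh.write(f"{letter}\t{row}\n")


def read_profiles(path, alphabet: Optional[AnnotationAlphabet] = None) -> dict[str, AnnotationProfile]:
    """Read a profile file back into a mapping id -> AnnotationProfile."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#alphabet"):
        raise FormatError(f"{path}:1: missing '#alphabet' header")
    letters = lines[0].split(maxsplit=1)[1].strip()
    if alphabet is None:
        if letters == "PLUM":
            alphabet = plum_alphabet()
        elif len(letters) == 1:
            alphabet = single_letter_alphabet(letters)
        else:
            raise FormatError(
                f"{path}:1: unknown alphabet {letters!r}; pass one explicitly"
            )
    if alphabet.name != letters:
        raise FormatError(
            f"{path}:1: file alphabet {letters!r} != expected {alphabet.name!r}"
        )
    out: dict[str, AnnotationProfile] = {}
    i = 1
    n_letters = len(alphabet)
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}:{i + 1}: expected '>id' line")
        rec_id = lines[i][1:].strip()
        rows = []
        for ai in range(n_letters):
            lineno = i + 1 + ai
            if lineno >= len(lines):
                raise FormatError(f"{path}:{lineno + 1}: truncated record {rec_id!r}")
            parts = lines[lineno].split("\t")
            if parts[0] != alphabet.letters[ai]:
                raise FormatError(
                    f"{path}:{lineno + 1}: expected letter {alphabet.letters[ai]!r}, "
                    f"got {parts[0]!r}"
                )
            try:
                rows.append([float(v) for v in parts[1:]])
            except ValueError:
                raise FormatError(f"{path}:{lineno + 1}: malformed probability") from None
        values = np.array(rows)
        colsums = values.sum(axis=0)
        bad = np.nonzero(np.abs(colsums - 1.0) > 1e-6)[0]
        if bad.size:
            raise FormatError(
                f"{path}:{i + 2}: record {rec_id!r} column {bad[0] + 1} sums to "
                f"{colsums[bad[0]]:.8f}, not 1"
            )
        # renormalize away the 6-decimal rounding so the profile invariant holds
        out[rec_id] = AnnotationProfile(alphabet=alphabet, values=values / colsums)
        i += 1 + n_letters
    return out


def read_dotbracket_samples(path) -> list[list[str]]:
    """Read sample files: one structure per line, blank line between records."""
    path = Path(path)
    groups: list[list[str]] = [[]]
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                if groups[-1]:
                    groups.append([])
                continue
            if set(line) - set("()."):
                raise FormatError(f"{path}:{lineno}: illegal dot-bracket character")
            depth = 0
            for ch in line:
                depth += ch == "("
                depth -= ch == ")"
                if depth < 0:
                    raise FormatError(f"{path}:{lineno}: unbalanced dot-bracket")
            if depth != 0:
                raise FormatError(f"{path}:{lineno}: unbalanced dot-bracket")
            groups[-1].append(line)
    if groups and not groups[-1]:
        groups.pop()
    return groups


# ---------------------------------------------------------------------------
# motif-model files
# ---------------------------------------------------------------------------

def write_model(path, model: MotifModel, affinity_map: AffinityMap) -> None:
    """Write a fitted model as plain text (10 significant digits)."""
    fmt = "%.10g"
    with open(path, "w") as fh:
        fh.write(f"width {model.width}\n")
        fh.write(f"alphabet {model.alphabet.name}\n")
        for bi, base in enumerate("ACGU"):
            vals = " ".join(fmt % v for v in model.theta[bi])
            fh.write(f"theta {base} {vals}\n")
        gam = " ".join(
            f"{letter}={fmt % g}"
            for letter, g in zip(model.alphabet.letters, model.gamma)
        )
        fh.write(f"gamma {gam}\n")
        fh.write(f"b_seq {fmt % model.b_seq}\n")
        fh.write(f"b_str {fmt % model.b_str}\n")
        fh.write(f"slope {fmt % affinity_map.slope}\n")
        fh.write(f"intercept {fmt % affinity_map.intercept}\n")
        if model.mean_context:
            fh.write("context_convention mean\n")


def read_model(path) -> tuple[MotifModel, AffinityMap]:
    path = Path(path)
    fields: dict[str, str] = {}
    theta_rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            key = parts[0]
            if key == "theta":
                if len(parts) < 3:
                    raise FormatError(f"{path}:{lineno}: malformed theta line")
                theta_rows[parts[1]] = [float(v) for v in parts[2:]]
            else:
                fields[key] = " ".join(parts[1:])
    try:
        width = int(fields["width"])
        letters = fields["alphabet"]
        theta = np.array([theta_rows[b] for b in "ACGU"])
        gamma_map = dict(kv.split("=") for kv in fields["gamma"].split())
        alphabet = plum_alphabet() if letters == "PLUM" else single_letter_alphabet(letters)
        gamma = np.array([float(gamma_map[a]) for a in alphabet.letters])
        model = MotifModel(
            width=width,
            theta=theta,
            gamma=gamma,
            b_seq=float(fields["b_seq"]),
            b_str=float(fields["b_str"]),
            alphabet=alphabet,
            mean_context=fields.get("context_convention", "sum") == "mean",
        )
        amap = AffinityMap(
            slope=float(fields["slope"]), intercept=float(fields["intercept"])
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing field {exc}") from exc
    return model, amap


# ---------------------------------------------------------------------------
# generic score/report tables
# ---------------------------------------------------------------------------

def write_table(path, columns: Sequence[str], rows: Sequence[dict]) -> None:
    """Write a TSV with a fixed column order and 6-decimal floats.

    The column order is taken from ``columns`` regardless of dict insertion
    order; missing cells become empty fields.  Round-trips through
    :func:`read_table` to printed precision.
    """
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, bool):
            return str(int(v))
        if isinstance(v, float):
            return f"{v:.6f}"
        return str(v)

    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(row.get(c)) for c in columns) + "\n")


def read_table(path) -> list[dict]:
    """Read a TSV written by :func:`write_table`; numbers become floats."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise FormatError(f"{path}:1: empty table")
    columns = lines[0].split("\t")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(columns):
            raise FormatError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(parts)}"
            )
        row = {}
        for c, v in zip(columns, parts):
            try:
                row[c] = float(v)
            except ValueError:
                row[c] = v
        rows.append(row)
    return rows


write_scores = write_table
write_reports = write_table


def write_pfm_meme(path, pfm: np.ndarray, name: str = "motif") -> None:
    """Write a 4 x w PFM as a MEME-minimal motif block (RNA alphabet)."""
    w = pfm.shape[1]
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write(f"MOTIF {name}\n")
        fh.write(f"letter-probability matrix: alength= 4 w= {w}\n")
        for j in range(w):
            fh.write(" ".join(f"{pfm[b, j]:.6f}" for b in range(4)) + "\n")
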