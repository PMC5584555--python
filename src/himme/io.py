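"""Readers and writers: FASTA input, gzip-TSV model matrices, score tables.

Model matrices and score tables are written as gzip-compressed tab-separated
text.  Header lines start with ``#`` and carry ``key=value`` metadata (k,
alphabet order, smoothing, source checksum, tool version, run parameters) so
a score run can detect mismatched matrices and every output references the
run that produced it.  Probabilities are serialized with ``%.17g`` so that
re-reading a written model reproduces it bit-exactly.
"""

from __future__ import annotations

import datetime
import gzip
import hashlib
import io as _stdio
import os
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO

from . import __version__
from .exceptions import MatrixFormatError
from .state_space import ALPHABET, KmerStateSpace

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------------------
# sequence input
# ---------------------------------------------------------------------------

def iter_sequences(source) -> Iterator[tuple[str, str]]:
    """Yield ``(id, sequence)`` pairs from a flexible sequence source.

    Accepts a FASTA path (plain or ``.gz``), an open text handle, a single
    sequence string, an iterable of strings, of ``(id, seq)`` tuples, or of
    Biopython ``SeqRecord`` objects.
    """
    if isinstance(source, (str, Path)):
        p = Path(source)
        try:
            is_file = p.exists()
        except OSError:  # e.g. a raw sequence far longer than a file name
            is_file = False
        if is_file:
            opener = gzip.open if str(p).endswith(".gz") else open
            with opener(p, "rt") as fh:
                for rec in SeqIO.parse(fh, "fasta"):
                    yield rec.id, str(rec.seq)
            return
        # A bare nucleotide string, not a file path.
        yield "seq1", str(source)
        return
    if isinstance(source, _stdio.IOBase):
        for rec in SeqIO.parse(source, "fasta"):
            yield rec.id, str(rec.seq)
        return
    for i, item in enumerate(source, start=1):
        if isinstance(item, str):
            yield f"seq{i}", item
        elif isinstance(item, tuple) and len(item) == 2:
            yield str(item[0]), str(item[1])
        else:  # SeqRecord
            yield item.id, str(item.seq)


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 70) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# run manifests
# ---------------------------------------------------------------------------

def file_md5(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(subcommand: str, params: dict, inputs: dict | None = None) -> dict:
    """Provenance record embedded in the header of every output file."""
    manifest = {
        "tool": f"himme {__version__}",
        "subcommand": subcommand,
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(timespec="seconds"),
    }
    for key, val in params.items():
        manifest[key] = val
    for name, p in (inputs or {}).items():
        if p is not None and Path(p).exists():
            manifest[f"{name}_md5"] = file_md5(p)
    return manifest


def _header_lines(manifest: dict | None) -> list[str]:
    if not manifest:
        return []
    return [f"#{k}={v}" for k, v in manifest.items()]


def _parse_headers(lines: list[str]) -> dict:
    meta = {}
    for line in lines:
        body = line[1:].strip()
        if "=" in body:
            key, val = body.split("=", 1)
            meta[key] = val
    return meta


def _atomic_gzip_writer(path):
    """Write to ``path + .tmp`` and rename on success: no partial outputs."""
    return _AtomicGzip(Path(path))


class _AtomicGzip:
    def __init__(self, path: Path):
        self.path = path
        self.tmp = path.with_name(path.name + ".tmp")

    def __enter__(self):
        self.fh = gzip.open(self.tmp, "wt")
        return self.fh

    def __exit__(self, exc_type, exc, tb):
        self.fh.close()
        if exc_type is None:
            os.replace(self.tmp, self.path)
        else:
            self.tmp.unlink(missing_ok=True)
        return False


# ---------------------------------------------------------------------------
# transition / emission matrices
# ---------------------------------------------------------------------------

def write_transition_model(tm, path, manifest: dict | None = None) -> None:
    from .transition import TransitionModel  # noqa: F401  (type only)

    space = tm.space
    meta = {
        "type": "transition",
        "k": space.k,
        "alphabet": space.alphabet,
        "pseudocount": repr(tm.pseudocount),
        **{f"training_{k}": v for k, v in (tm.training_meta or {}).items()},
    }
    if manifest:
        meta.update(manifest)
    with _atomic_gzip_writer(path) as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        cols = "\t".join(space.decode(j) for j in range(space.cardinality))
        fh.write("kmer\tpi0\t" + cols + "\n")
        for s in range(space.cardinality):
            row = "\t".join(_FLOAT_FMT % v for v in tm.trans[s])
            fh.write(f"{space.decode(s)}\t{_FLOAT_FMT % tm.pi0[s]}\t{row}\n")


def read_transition_model(path):
    from .transition import TransitionModel

    with gzip.open(path, "rt") as fh:
        lines = fh.read().splitlines()
    headers = [l for l in lines if l.startswith("#")]
    body = [l for l in lines if l and not l.startswith("#")]
    meta = _parse_headers(headers)
    if meta.get("type") != "transition" or "k" not in meta:
        raise MatrixFormatError(f"{path} is not a himme transition matrix file")
    k = int(meta["k"])
    space = KmerStateSpace(k)
    if len(body) != space.cardinality + 1:
        raise MatrixFormatError(
            f"expected {space.cardinality} state rows for k={k}, found {len(body) - 1}"
        )
    pi0 = np.empty(space.cardinality)
    trans = np.empty((space.cardinality, space.cardinality))
    for line in body[1:]:
        parts = line.split("\t")
        if len(parts) != space.cardinality + 2:
            raise MatrixFormatError(f"malformed row in {path}: {parts[0]!r}")
        s = space.encode(parts[0])
        pi0[s] = float(parts[1])
        trans[s] = [float(x) for x in parts[2:]]
    training_meta = {
        key[len("training_"):]: val for key, val in meta.items() if key.startswith("training_")
    }
    return TransitionModel(
        space=space,
        pi0=pi0,
        trans=trans,
        pseudocount=float(meta.get("pseudocount", "nan")),
        training_meta=training_meta,
    )


def write_emission_model(em, path, manifest: dict | None = None) -> None:
    meta = {
        "type": "emission",
        "alphabet": ALPHABET,
        "source": em.source,
        **{f"param_{k}": v for k, v in (em.params or {}).items()},
    }
    if manifest:
        meta.update(manifest)
    with _atomic_gzip_writer(path) as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("base\t" + "\t".join(ALPHABET) + "\n")
        for i, b in enumerate(ALPHABET):
            fh.write(b + "\t" + "\t".join(_FLOAT_FMT % v for v in em.base_emission[i]) + "\n")


def read_emission_model(path):
    from .emission import EmissionModel

    with gzip.open(path, "rt") as fh:
        lines = fh.read().splitlines()
    meta = _parse_headers([l for l in lines if l.startswith("#")])
    body = [l for l in lines if l and not l.startswith("#")]
    if meta.get("type") != "emission" or len(body) != 5:
        raise MatrixFormatError(f"{path} is not a himme emission matrix file")
    mat = np.empty((4, 4))
    for line in body[1:]:
        parts = line.split("\t")
        if len(parts) != 5 or parts[0] not in ALPHABET:
            raise MatrixFormatError(f"malformed emission row in {path}")
        mat[ALPHABET.index(parts[0])] = [float(x) for x in parts[1:]]
    params = {key[len("param_"):]: val for key, val in meta.items() if key.startswith("param_")}
    return EmissionModel(base_emission=mat, source=meta.get("source", "manual"), params=params)


# ---------------------------------------------------------------------------
# per-contig score tables
# ---------------------------------------------------------------------------

_SCORE_COLUMNS = ("contig_id", "length", "raw_score", "normalized_score", "m", "flags")


def write_scores(scores, path, k: int, manifest: dict | None = None) -> None:
    meta = {"type": "scores", "k": k}
    if manifest:
        meta.update(manifest)
    with _atomic_gzip_writer(path) as fh:
        for line in _header_lines(meta):
            fh.write(line + "\n")
        fh.write("\t".join(_SCORE_COLUMNS) + "\n")
        for sc in scores:
            raw = "NA" if sc.raw_score is None else _FLOAT_FMT % sc.raw_score
            norm = "NA" if sc.normalized_score is None else _FLOAT_FMT % sc.normalized_score
            flags = ",".join(sorted(sc.flags)) if sc.flags else "."
            fh.write(f"{sc.contig_id}\t{sc.length_nt}\t{raw}\t{norm}\t{sc.m}\t{flags}\n")


def read_scores(path):
    from .scoring import ContigScore

    with gzip.open(path, "rt") as fh:
        lines = fh.read().splitlines()
    meta = _parse_headers([l for l in lines if l.startswith("#")])
    body = [l for l in lines if l and not l.startswith("#")]
    if meta.get("type") != "scores" or not body or body[0].split("\t") != list(_SCORE_COLUMNS):
        raise MatrixFormatError(f"{path} is not a himme score file")
    scores = []
    for line in body[1:]:
        cid, length, raw, norm, m, flags = line.split("\t")
        scores.append(
            ContigScore(
                contig_id=cid,
                length_nt=int(length),
                raw_score=None if raw == "NA" else float(raw),
                normalized_score=None if norm == "NA" else float(norm),
                m=int(m),
                flags=frozenset() if flags == "." else frozenset(flags.split(",")),
            )
        )
    return scores, meta


def read_reference_scores(path) -> np.ndarray:
    """Normalized scores for a reference distribution.

    Accepts either a himme score table (the ``normalized_score`` column is
    used; unscored contigs are dropped) or a plain text file with one score
    per line.
    """
    try:
        scores, _ = read_scores(path)
        return np.array([s.normalized_score for s in scores if s.normalized_score is not None])
    except (MatrixFormatError, OSError, gzip.BadGzipFile):
        pass
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        vals = [float(tok) for tok in fh.read().split()]
    return np.asarray(vals, dtype=float)
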