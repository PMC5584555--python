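"""Per-contig scoring of an assembly."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .emission import EmissionModel
from .forward import forward_log_likelihood, normalized_score
from .io import iter_sequences
from .state_space import tokenize_sequence
from .transition import TransitionModel

#: Contig flags: no complete k-mer window / ambiguous windows dropped /
#: observation impossible under the model (scores are -inf).
FLAG_TOO_SHORT = "too_short"
FLAG_SKIPPED_WINDOWS = "skipped_windows"
FLAG_ZERO_PROBABILITY = "zero_probability"


@dataclass(frozen=True)
class ContigScore:
    """Score record for one contig.

    ``raw_score`` is ``log P[Y; Theta]`` and ``normalized_score`` the
    per-frame log-likelihood ``raw_score / (k * m)``; both are ``None`` for
    contigs with no scoreable k-mer (flagged ``too_short``).
    """

    contig_id: str
    length_nt: int
    raw_score: float | None
    normalized_score: float | None
    m: int
    flags: frozenset[str] = frozenset()


def score_sequence(
    contig_id: str, seq: str, tm: TransitionModel, em: EmissionModel
) -> ContigScore:
    """Score a single nucleotide sequence under the model."""
    obs = tokenize_sequence(seq, tm.space)
    flags = set()
    if obs.skipped > 0:
        flags.add(FLAG_SKIPPED_WINDOWS)
    if obs.m == 0:
        flags.add(FLAG_TOO_SHORT)
        return ContigScore(contig_id, len(seq), None, None, 0, frozenset(flags))
    fr = forward_log_likelihood(obs, tm, em)
    if fr.log_likelihood == float("-inf"):
        flags.add(FLAG_ZERO_PROBABILITY)
    return ContigScore(
        contig_id,
        len(seq),
        fr.log_likelihood,
        normalized_score(fr, tm.space.k),
        obs.m,
        frozenset(flags),
    )


def score_contigs(assembly, tm: TransitionModel, em: EmissionModel) -> list[ContigScore]:
    """One :class:`ContigScore` per assembly record, input order preserved.

    ``assembly`` is anything :func:`himme.io.iter_sequences` accepts (FASTA
    path, handle, records).  Raises ``ValueError`` on an empty input.
    """
    scores = [score_sequence(cid, seq, tm, em) for cid, seq in iter_sequences(assembly)]
    if not scores:
        raise ValueError("assembly contains no sequence records")
    return scores


def scores_to_dataframe(scores: list[ContigScore]):
    """Score records as a pandas DataFrame (one row per contig)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "contig_id": [s.contig_id for s in scores],
            "length": [s.length_nt for s in scores],
            "raw_score": [np.nan if s.raw_score is None else s.raw_score for s in scores],
            "normalized_score": [
                np.nan if s.normalized_score is None else s.normalized_score for s in scores
            ],
            "m": [s.m for s in scores],
            "flags": [",".join(sorted(s.flags)) if s.flags else "" for s in scores],
        }
    )
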