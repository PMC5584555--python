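"""Model/Results facade: the main user-facing API.

`KmerHMM` bundles the training data with the model configuration (k-mer
size, smoothing, emission matrix); `fit()` estimates the transition matrix
and returns a `KmerHMMResults` object that scores contigs, simulates
sequences, builds reference distributions, and produces assembly summaries.

Example
-------
>>> from himme import KmerHMM, build_emission_manual
>>> model = KmerHMM.from_fasta("reference.fa", k=3,
...                            emission=build_emission_manual(0.85))
>>> res = model.fit()
>>> scores = res.score_contigs("assembly.fa")
>>> ref = res.reference_distribution(n=30000, length=1000, seed=7)
>>> res.summarize_assembly(scores, ref).himme_coeff
"""

from __future__ import annotations

from pathlib import Path

from .emission import EmissionModel, build_emission_manual, state_entropy
from .scoring import ContigScore, score_contigs, scores_to_dataframe
from .state_space import KmerStateSpace
from .summary import (
    AssemblySummary,
    ReferenceDistribution,
    build_reference_distribution,
    summarize_assembly,
)
from .transition import TransitionModel, learn_transition_model


class KmerHMM:
    """A k-mer hidden Markov model to be estimated from training sequences.

    Parameters
    ----------
    training : FASTA path, handle, string, or iterable of sequences/records
        The prior knowledge the model is trained on: a reference genome, a
        related species' genome, or a gene set.
    k : int
        k-mer size of the hidden states (state space has ``4**k`` states).
    pseudocount : float
        Additive smoothing for transition estimation.
    emission : EmissionModel, optional
        Per-base substitution matrix; defaults to the identity matrix
        (complete confidence in the observed bases — the Markov-chain limit).
    counting : {"sliding", "chunked"}
        Transition-pair counting mode during training.
    """

    def __init__(
        self,
        training,
        k: int = 3,
        pseudocount: float = 1.0,
        emission: EmissionModel | None = None,
        counting: str = "sliding",
    ):
        self.training = training
        self.space = KmerStateSpace(k)
        self.pseudocount = pseudocount
        self.emission = emission if emission is not None else build_emission_manual(1.0)
        self.counting = counting

    @classmethod
    def from_fasta(cls, path, **kwargs) -> "KmerHMM":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        return cls(path, **kwargs)

    @property
    def k(self) -> int:
        return self.space.k

    def fit(self) -> "KmerHMMResults":
        """Estimate the transition matrix and initial distribution."""
        tm = learn_transition_model(
            self.training, self.space, pseudocount=self.pseudocount, mode=self.counting
        )
        return KmerHMMResults(self, tm, self.emission)


class KmerHMMResults:
    """Fitted model: estimated transition matrix plus the emission matrix."""

    def __init__(self, model: KmerHMM, transition_model: TransitionModel, emission: EmissionModel):
        self.model = model
        self.transition_model = transition_model
        self.emission_model = emission

    @property
    def k(self) -> int:
        return self.model.k

    @property
    def space(self) -> KmerStateSpace:
        return self.model.space

    # -- scoring ----------------------------------------------------------

    def score_contigs(self, assembly) -> list[ContigScore]:
        """Per-contig forward log-likelihoods and normalized scores."""
        return score_contigs(assembly, self.transition_model, self.emission_model)

    def score_dataframe(self, assembly):
        return scores_to_dataframe(self.score_contigs(assembly))

    # -- simulation -------------------------------------------------------

    def simulate(self, n: int, length: int, seed=None) -> list[str]:
        """Draw observed sequences from the fitted model (chain + emission noise)."""
        from .simulate import sample_from_model

        return sample_from_model(self.transition_model, self.emission_model, n, length, seed)

    def reference_distribution(
        self, scores=None, n: int = 30_000, length: int = 1_000, seed: int = 0
    ) -> ReferenceDistribution:
        """Reference score distribution, from given scores or simulated."""
        if scores is not None:
            return build_reference_distribution(scores)
        return build_reference_distribution(
            model=self.transition_model,
            emission=self.emission_model,
            n=n,
            length=length,
            seed=seed,
        )

    def summarize_assembly(
        self, scores, ref: ReferenceDistribution, strict: bool = True
    ) -> AssemblySummary:
        return summarize_assembly(scores, ref, self.k, strict=strict)

    # -- reporting --------------------------------------------------------

    def summary(self) -> str:
        """Human-readable description of the fitted model."""
        tm = self.transition_model
        meta = tm.training_meta
        pi0_entropy = state_entropy(tm.pi0)
        max_entropy = self.k * 1.3862943611198906  # k * ln 4
        lines = [
            "k-mer hidden Markov model",
            "=" * 48,
            f"k-mer size:               {self.k}",
            f"hidden states (4^k):      {self.space.cardinality}",
            f"training sequences:       {meta.get('n_sequences', '?')}",
            f"training bases:           {meta.get('n_bases', '?')}",
            f"transitions counted:      {meta.get('n_transitions', '?')}",
            f"counting mode:            {meta.get('mode', '?')}",
            f"pseudocount:              {tm.pseudocount:g}",
            f"pi0 entropy (nats):       {pi0_entropy:.4f} / {max_entropy:.4f} max",
            f"emission source:          {self.emission_model.source}",
            f"emission diagonal:        "
            + ", ".join(f"{v:.3f}" for v in self.emission_model.base_emission.diagonal()),
            "=" * 48,
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<KmerHMMResults k={self.k}, states={self.space.cardinality}>"
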