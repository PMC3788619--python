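"""Kinase binding-specificity models and the Matrix Similarity Score.

A kinase's sequence preference is modeled as a 15-position × 20-amino-acid
position weight matrix (PWM) with the phospho-acceptor at position 8.  A
candidate 15-mer is compared to a PWM with the Matrix Similarity Score (MSS)
of the MATCH motif-scanning framework, adapted to the amino-acid alphabet:

    MSS = (Current - Min) / (Max - Min)

where ``Current = Σ_i I(i) · p_i(a_i)`` over the 14 flanking columns (the
central column is excluded so the score reflects flank recognition only),
``Min``/``Max`` substitute each column's minimum/maximum probability, and
``I(i) = Σ_a p_i(a) · ln(20 · p_i(a))`` is the column information weight.

Statistical significance of an MSS value is the empirical fraction of a
background peptide set — phosphosites annotated to *other* kinases — scoring
equal or greater.  Training sets are cleaned by iterative outlier removal
(members with background p above a cutoff are dropped until convergence) and
models are validated by ten-fold cross-validated AUROC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .annotation import AA_INDEX, AMINO_ACIDS, CENTER, PAD, WINDOW
from .errors import DegenerateModelError, FormatError

N_AA = len(AMINO_ACIDS)
_FLANK_COLS = np.array([i for i in range(WINDOW) if i != CENTER])


def encode_peptides(peptides: Sequence[str]) -> np.ndarray:
    """Encode 15-mers as an (n, 15) int array; terminal pads become -1."""
    arr = np.empty((len(peptides), WINDOW), dtype=np.int64)
    for r, pep in enumerate(peptides):
        if len(pep) != WINDOW:
            raise FormatError(f"peptide {pep!r} is not {WINDOW} residues")
        for c, aa in enumerate(pep):
            if aa == PAD:
                arr[r, c] = -1
            else:
                idx = AA_INDEX.get(aa)
                if idx is None:
                    raise FormatError(
                        f"peptide {pep!r}: residue {aa!r} outside the "
                        "20-letter alphabet")
                arr[r, c] = idx
    return arr


def information_weights(probs: np.ndarray) -> np.ndarray:
    """Per-column information I(i) = Σ_a p·ln(20p), with 0·ln0 = 0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(probs > 0, probs * np.log(N_AA * probs), 0.0)
    return np.maximum(terms.sum(axis=0), 0.0)


@dataclass
class KinasePwm:
    """A 15×20 kinase binding model with its training provenance."""

    kinase: str
    probs: np.ndarray  # (20, 15); columns sum to 1
    info_weights: np.ndarray  # (15,)
    training_peptides: list[str]
    n_initial: int
    n_retained: int
    auroc: float | None = None
    retained: bool = False

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_AA, WINDOW):
            raise FormatError(
                f"PWM shape {self.probs.shape} != ({N_AA}, {WINDOW})")
        sums = self.probs.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise FormatError("PWM columns must sum to 1")


def build_pwm(kinase: str, peptides: Sequence[str],
              pseudocount: float = 0.01) -> KinasePwm:
    """Estimate a PWM from aligned 15-mer binding peptides.

    Terminal ``_`` pads contribute no count; each column normalizes over the
    peptides actually observed there, plus the pseudocount.  A column with no
    observations is uniform.
    """
    if len(peptides) < 1:
        raise FormatError("at least one training peptide required")
    enc = encode_peptides(peptides)
    counts = np.zeros((N_AA, WINDOW), dtype=float)
    for c in range(WINDOW):
        col = enc[:, c]
        col = col[col >= 0]
        if col.size:
            counts[:, c] = np.bincount(col, minlength=N_AA)
    n_per_col = counts.sum(axis=0)
    denom = n_per_col + N_AA * pseudocount
    probs = np.empty_like(counts)
    for c in range(WINDOW):
        if denom[c] > 0:
            probs[:, c] = (counts[:, c] + pseudocount) / denom[c]
        else:
            probs[:, c] = 1.0 / N_AA
    return KinasePwm(kinase, probs, information_weights(probs),
                     list(peptides), len(peptides), len(peptides))


def _score_terms(model: KinasePwm, use_info_weights: bool = True):
    weights = (model.info_weights if use_info_weights
               else np.ones(WINDOW))
    col_min = model.probs.min(axis=0)
    col_max = model.probs.max(axis=0)
    return weights, col_min, col_max


def mss_scores(model: KinasePwm, encoded: np.ndarray,
               use_info_weights: bool = True) -> np.ndarray:
    """Vectorized MSS over an (n, 15) encoded peptide array."""
    weights, col_min, col_max = _score_terms(model, use_info_weights)
    n = encoded.shape[0]
    cur = np.zeros(n)
    mn = np.zeros(n)
    mx = np.zeros(n)
    for c in _FLANK_COLS:
        w = weights[c]
        col = encoded[:, c]
        pad = col < 0
        p = model.probs[np.where(pad, 0, col), c]
        uniform = w / N_AA
        cur += np.where(pad, uniform, w * p)
        mn += np.where(pad, uniform, w * col_min[c])
        mx += np.where(pad, uniform, w * col_max[c])
    span = mx - mn
    if np.any(span <= 1e-12):
        raise DegenerateModelError(
            f"model {model.kinase}: Max == Min over scored columns")
    return np.clip((cur - mn) / span, 0.0, 1.0)


def mss(model: KinasePwm, peptide: str,
        use_info_weights: bool = True) -> float:
    """Matrix Similarity Score of one 15-mer against a PWM, in [0, 1].

    The central column is never scored, so any substitution of the
    phospho-residue leaves the MSS unchanged.  Pad positions contribute the
    uniform expectation I(i)/20 and are excluded from the Min/Max extremes.
    """
    return float(mss_scores(model, encode_peptides([peptide]),
                            use_info_weights)[0])


@dataclass(frozen=True)
class MssResult:
    score: float
    p_value: float
    n_background: int


class MssBackground:
    """Cached background MSS distribution for one model.

    The background is the phosphosite set with known kinases *not*
    associated to this model's kinase; the empirical p-value of a score is
    the fraction of background peptides scoring equal or greater.
    """

    def __init__(self, model: KinasePwm, peptides: Sequence[str],
                 use_info_weights: bool = True, smooth: bool = False):
        if len(peptides) == 0:
            raise FormatError("empirical p-value requires a non-empty "
                              "background")
        self.model = model
        self.n = len(peptides)
        self.smooth = smooth
        self._sorted = np.sort(
            mss_scores(model, encode_peptides(peptides), use_info_weights))

    def p_value(self, score: float) -> float:
        ge = self.n - int(np.searchsorted(self._sorted, score, side="left"))
        if self.smooth:
            return (ge + 1) / (self.n + 1)
        return ge / self.n

    def p_values(self, scores: np.ndarray) -> np.ndarray:
        ge = self.n - np.searchsorted(self._sorted, scores, side="left")
        if self.smooth:
            return (ge + 1) / (self.n + 1)
        return ge / self.n


def empirical_p(model: KinasePwm, score: float,
                background: Sequence[str] | MssBackground,
                use_info_weights: bool = True) -> MssResult:
    """Empirical p-value of an MSS against a background peptide set."""
    bg = (background if isinstance(background, MssBackground)
          else MssBackground(model, background, use_info_weights))
    return MssResult(score, bg.p_value(score), bg.n)


def refine_pwm(kinase: str, peptides: Sequence[str],
               background: Sequence[str], cutoff: float = 0.2,
               pseudocount: float = 0.01, min_training_seqs: int = 20,
               use_info_weights: bool = True,
               leave_one_out: bool = False) -> KinasePwm:
    """Iteratively remove outlier training peptides until convergence.

    Each round builds a PWM from the surviving set, computes every member's
    empirical p-value against the (kinase-disjoint) background, and drops
    members with p above the cutoff.  The loop stops when no member is
    dropped; the model is flagged non-retained when fewer than
    ``min_training_seqs`` peptides survive.  Deterministic and guaranteed to
    terminate — the surviving set strictly shrinks or the loop exits.
    """
    current = list(peptides)
    n_initial = len(current)
    model = build_pwm(kinase, current, pseudocount)
    while current:
        model = build_pwm(kinase, current, pseudocount)
        bg = MssBackground(model, background, use_info_weights)
        if leave_one_out:
            ps = np.array([
                bg.p_value(mss(build_pwm(
                    kinase, current[:i] + current[i + 1:], pseudocount), pep,
                    use_info_weights))
                for i, pep in enumerate(current)])
        else:
            scores = mss_scores(model, encode_peptides(current),
                                use_info_weights)
            ps = bg.p_values(scores)
        keep = ps <= cutoff
        if keep.all():
            break
        current = [pep for pep, k in zip(current, keep) if k]
    model.training_peptides = current
    model.n_initial = n_initial
    model.n_retained = len(current)
    model.retained = len(current) >= min_training_seqs
    return model


def crossvalidate_auroc(kinase: str, peptides: Sequence[str],
                        negatives: Sequence[str], folds: int = 10,
                        seed: int = 0, pseudocount: float = 0.01,
                        use_info_weights: bool = True) -> float:
    """Ten-fold cross-validated AUROC of a kinase model.

    Peptides are shuffled with the seed and split into folds; each fold's
    PWM is built on the held-in peptides and scores the held-out positives
    plus all negatives.  The AUROC is computed over the pooled fold scores
    with midrank tie handling.
    """
    if len(negatives) == 0:
        raise FormatError("negatives must be non-empty")
    if folds > len(peptides):
        raise FormatError(
            f"{folds} folds for {len(peptides)} peptides")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(peptides))
    fold_idx = np.array_split(order, folds)
    neg_enc = encode_peptides(negatives)
    scores: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for held_out in fold_idx:
        held = set(held_out.tolist())
        train = [peptides[i] for i in range(len(peptides)) if i not in held]
        model = build_pwm(kinase, train, pseudocount)
        pos_enc = encode_peptides([peptides[i] for i in held_out])
        pos_scores = mss_scores(model, pos_enc, use_info_weights)
        neg_scores = mss_scores(model, neg_enc, use_info_weights)
        scores.extend([pos_scores, neg_scores])
        labels.extend([np.ones(len(pos_scores)), np.zeros(len(neg_scores))])
    return float(roc_auc_score(np.concatenate(labels),
                               np.concatenate(scores)))


def evaluate_kinase(kinase: str, peptides: Sequence[str],
                    background: Sequence[str], negatives: Sequence[str],
                    config) -> KinasePwm:
    """Refine, cross-validate and gate one kinase model.

    Applies the full retention policy: at least ``min_training_seqs``
    refined peptides and a cross-validated AUROC of at least ``auroc_min``.
    """
    if len(peptides) < config.min_training_seqs:
        model = build_pwm(kinase, peptides, config.pseudocount)
        model.retained = False
        return model
    model = refine_pwm(kinase, peptides, background,
                       cutoff=config.outlier_cutoff,
                       pseudocount=config.pseudocount,
                       min_training_seqs=config.min_training_seqs,
                       use_info_weights=config.use_info_weights,
                       leave_one_out=config.refine_leave_one_out)
    if not model.retained:
        return model
    folds = min(10, model.n_retained)
    model.auroc = crossvalidate_auroc(
        kinase, model.training_peptides, negatives, folds=folds,
        seed=config.rng_seed, pseudocount=config.pseudocount,
        use_info_weights=config.use_info_weights)
    model.retained = model.auroc >= config.auroc_min
    return model
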