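"""Donor/acceptor splice-site scoring models.

Two trainable model families are provided, mirroring the two families that
dominate splice-site signal scoring:

* :class:`PwmSpliceModel` — a position weight matrix over the consensus
  window, scored on a min-max normalized 0-100 scale (the Shapiro-Senapathy
  convention), so the score has a finite range.
* :class:`MaxEntSpliceModel` — the maximum-entropy distribution over
  window sequences constrained to match low-order positional marginals
  (all singletons, plus adjacent pairs and triples depending on
  ``constraint_order``).  Because the constraint subsets form a chain, the
  exact entropy maximizer is the Markov chain of order ``constraint_order-1``
  built from the pseudocounted empirical pair/triple tables; the fit is
  therefore closed-form and the post-fit marginal residuals are checked
  against ``tol``.  Scores are log2 odds against a background model and are
  unbounded in both directions.

Both estimators follow the scikit-learn protocol: ``fit`` on a list of
equal-length DNA strings, ``transform`` to per-sequence scores, fitted
attributes carry a trailing underscore, and models serialize to versioned
JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .regions import RegionDefinition, region_for

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_LOG_FLOOR = 1e-300  # keeps log finite when pseudocount is zero


class ConvergenceError(RuntimeError):
    """Raised when fitted marginals fail to match the empirical constraints."""

    def __init__(self, residual: float, tol: float):
        super().__init__(
            f"worst marginal residual {residual:.3g} exceeds tolerance {tol:.3g}"
        )
        self.residual = residual
        self.tol = tol


def encode_sequence(seq: str, length: int | None = None) -> np.ndarray:
    """Map a DNA string to base indices, rejecting non-ACGT symbols.

    Lowercase is accepted and uppercased; N and other IUPAC ambiguity codes
    are rejected with the offending position reported (0-based).
    """
    s = seq.upper()
    if length is not None and len(s) != length:
        raise ValueError(f"sequence length {len(s)} != expected {length}")
    out = np.empty(len(s), dtype=np.int64)
    for i, b in enumerate(s):
        idx = _BASE_INDEX.get(b)
        if idx is None:
            raise ValueError(f"non-ACGT symbol {b!r} at position {i}")
        out[i] = idx
    return out


def _encode_training_set(sequences) -> np.ndarray:
    seqs = list(sequences)
    if not seqs:
        raise ValueError("empty training set")
    length = len(seqs[0])
    rows = []
    for j, s in enumerate(seqs):
        if len(s) != length:
            raise ValueError(
                f"ragged training set: sequence {j} has length {len(s)}, expected {length}"
            )
        rows.append(encode_sequence(s, length))
    return np.vstack(rows)


def load_site_sequences(path) -> list:
    """Read training sequences from FASTA or plain one-per-line text."""
    text = Path(path).read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        return [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
    return [line.strip() for line in text.splitlines() if line.strip()]


class PwmSpliceModel(TransformerMixin, BaseEstimator):
    """Position weight matrix splice-site scorer on a 0-100 scale.

    Parameters
    ----------
    site_kind : {"donor", "acceptor"}
        Selects the consensus window (donor 11 nt, acceptor 14 nt).
    pseudocount : float, default 0.5
        Added to every cell of the count matrix before normalization, so all
        frequencies are positive with small training sets.

    Attributes
    ----------
    frequencies_ : ndarray of shape (L, 4)
        Per-position base frequencies; each row sums to 1.
    min_logsum_, max_logsum_ : float
        Normalization constants: the sums over positions of the min/max
        log-frequency, anchoring scores 0 and 100.
    """

    def __init__(self, site_kind: str = "donor", pseudocount: float = 0.5):
        self.site_kind = site_kind
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        region = region_for(self.site_kind)
        enc = _encode_training_set(X)
        n, L = enc.shape
        # Canonical windows are 11 nt (donor) / 14 nt (acceptor); other
        # lengths are accepted so models can be trained on ad-hoc windows.
        self.region_ = region if L == len(region) else None
        counts = np.zeros((L, 4))
        for p in range(L):
            counts[p] = np.bincount(enc[:, p], minlength=4)
        self.frequencies_ = (counts + self.pseudocount) / (n + 4 * self.pseudocount)
        logf = np.log(np.maximum(self.frequencies_, _LOG_FLOOR))
        self.min_logsum_ = float(logf.min(axis=1).sum())
        self.max_logsum_ = float(logf.max(axis=1).sum())
        self.length_ = L
        self.n_sequences_ = n
        return self

    def log_likelihood(self, seq: str) -> float:
        check_is_fitted(self, "frequencies_")
        enc = encode_sequence(seq, self.length_)
        logf = np.log(np.maximum(self.frequencies_, _LOG_FLOOR))
        return float(logf[np.arange(self.length_), enc].sum())

    def score_sequence(self, seq: str) -> float:
        """Min-max normalized score in [0, 100]."""
        ll = self.log_likelihood(seq)
        span = self.max_logsum_ - self.min_logsum_
        if span <= 0:  # every position uniform: no signal to normalize
            return 100.0
        return float(np.clip(100.0 * (ll - self.min_logsum_) / span, 0.0, 100.0))

    def transform(self, X) -> np.ndarray:
        return np.array([self.score_sequence(s) for s in X])

    @property
    def score_range(self):
        return (0.0, 100.0)

    def consensus(self) -> str:
        check_is_fitted(self, "frequencies_")
        return "".join(ALPHABET[i] for i in self.frequencies_.argmax(axis=1))

    def to_json(self) -> str:
        check_is_fitted(self, "frequencies_")
        return json.dumps(
            {
                "format": "scsnv-pwm",
                "version": 1,
                "site_kind": self.site_kind,
                "pseudocount": self.pseudocount,
                "frequencies": self.frequencies_.tolist(),
                "min_logsum": self.min_logsum_,
                "max_logsum": self.max_logsum_,
                "n_sequences": self.n_sequences_,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PwmSpliceModel":
        d = json.loads(text)
        if d.get("format") != "scsnv-pwm":
            raise ValueError("not a scsnv PWM model file")
        model = cls(site_kind=d["site_kind"], pseudocount=d["pseudocount"])
        model.frequencies_ = np.asarray(d["frequencies"], dtype=float)
        model.min_logsum_ = d["min_logsum"]
        model.max_logsum_ = d["max_logsum"]
        model.length_ = model.frequencies_.shape[0]
        canonical = region_for(d["site_kind"])
        model.region_ = canonical if model.length_ == len(canonical) else None
        model.n_sequences_ = d["n_sequences"]
        return model


class MaxEntSpliceModel(TransformerMixin, BaseEstimator):
    """Maximum-entropy splice-site model with low-order marginal constraints.

    The constraint set is all singleton positions (``constraint_order=1``),
    plus adjacent pairs (2) or adjacent triples (3).  On a chain of adjacent
    subsets the entropy maximizer matching pseudocounted empirical marginals
    is the corresponding Markov chain, which is what ``fit`` constructs; the
    worst constraint residual is verified against ``tol`` and a
    :class:`ConvergenceError` raised if it is exceeded.

    Scores are ``log2(P_model(seq) / P_background(seq))``.  The background is
    uniform (0.25 per base) by default, or the training set's 0th-order
    composition with ``background="composition"``.
    """

    def __init__(
        self,
        site_kind: str = "donor",
        constraint_order: int = 2,
        pseudocount: float = 0.5,
        background: str = "uniform",
        tol: float = 1e-8,
        max_iter: int = 1000,
    ):
        self.site_kind = site_kind
        self.constraint_order = constraint_order
        self.pseudocount = pseudocount
        self.background = background
        self.tol = tol
        self.max_iter = max_iter

    # -- fitting -----------------------------------------------------------

    def fit(self, X, y=None):
        if self.constraint_order not in (1, 2, 3):
            raise ValueError("constraint_order must be 1, 2 or 3")
        enc = _encode_training_set(X)
        n, L = enc.shape
        region = region_for(self.site_kind)
        if L < self.constraint_order:
            raise ValueError("constraint_order exceeds sequence length")
        pc = self.pseudocount
        self.length_ = L
        self.region_ = region if L == len(region) else None

        counts1 = np.zeros((L, 4))
        for p in range(L):
            counts1[p] = np.bincount(enc[:, p], minlength=4)

        if self.constraint_order >= 2:
            pairs = np.zeros((L - 1, 4, 4))
            for p in range(L - 1):
                np.add.at(pairs[p], (enc[:, p], enc[:, p + 1]), 1.0)
            self.pairs_ = (pairs + pc) / (n + 16 * pc)
        if self.constraint_order == 3:
            triples = np.zeros((L - 2, 4, 4, 4))
            for p in range(L - 2):
                np.add.at(triples[p], (enc[:, p], enc[:, p + 1], enc[:, p + 2]), 1.0)
            self.triples_ = (triples + pc) / (n + 64 * pc)

        # The singleton targets must be coherent with the higher-order
        # tables' own pseudocounting; with order >= 2 they are the marginals
        # the pair/triple tables imply (uniform per-cell pseudocounts make
        # adjacent tables agree on shared positions, so this is well posed).
        if self.constraint_order == 1:
            self.singles_ = (counts1 + pc) / (n + 4 * pc)
        elif self.constraint_order == 2:
            sing = [self.pairs_[0].sum(axis=1)]
            sing += [self.pairs_[p].sum(axis=0) for p in range(L - 1)]
            self.singles_ = np.vstack(sing)
        else:
            sing = [
                self.triples_[0].sum(axis=(1, 2)),
                self.triples_[0].sum(axis=(0, 2)),
            ]
            sing += [self.triples_[p].sum(axis=(0, 1)) for p in range(L - 2)]
            self.singles_ = np.vstack(sing)

        if self.background == "uniform":
            self.background_ = np.full((L, 4), 0.25)
        elif self.background == "composition":
            comp = counts1.sum(axis=0) / counts1.sum()
            self.background_ = np.tile(comp, (L, 1))
        else:
            bg = np.asarray(self.background, dtype=float)
            if bg.shape != (L, 4):
                raise ValueError("custom background must have shape (L, 4)")
            self.background_ = bg

        self._check_marginals()
        return self

    def _chain_marginals(self) -> np.ndarray:
        """Per-position marginals implied by the fitted chain (forward pass)."""
        L = self.length_
        if self.constraint_order == 1:
            return self.singles_.copy()
        out = np.zeros((L, 4))
        if self.constraint_order == 2:
            out[0] = self.pairs_[0].sum(axis=1)
            for p in range(L - 1):
                cond = self.pairs_[p] / self.pairs_[p].sum(axis=1, keepdims=True)
                out[p + 1] = out[p] @ cond
            return out
        # order 3: track pairwise state (p, p+1)
        state = self.triples_[0].sum(axis=2)  # joint of positions 0,1
        out[0] = state.sum(axis=1)
        out[1] = state.sum(axis=0)
        for p in range(L - 2):
            cond = self.triples_[p] / self.triples_[p].sum(axis=2, keepdims=True)
            nxt = np.einsum("ab,abc->bc", state, cond)
            out[p + 2] = nxt.sum(axis=0)
            state = nxt
        return out

    def _check_marginals(self):
        implied = self._chain_marginals()
        residual = float(np.abs(implied - self.singles_).max())
        self.marginal_residual_ = residual
        self.n_iter_ = 1  # closed-form fit
        if residual > max(self.tol, 1e-8):
            raise ConvergenceError(residual, self.tol)

    # -- scoring -----------------------------------------------------------

    def log_prob(self, seq: str) -> float:
        """Natural-log probability of ``seq`` under the fitted distribution."""
        check_is_fitted(self, "singles_")
        s = encode_sequence(seq, self.length_)
        if self.constraint_order == 1:
            return float(
                np.log(self.singles_[np.arange(self.length_), s]).sum()
            )
        if self.constraint_order == 2:
            lp = np.log(self.pairs_[0][s[0], s[1]])
            for p in range(1, self.length_ - 1):
                row = self.pairs_[p][s[p]]
                lp += np.log(row[s[p + 1]] / row.sum())
            return float(lp)
        lp = np.log(self.triples_[0][s[0], s[1], s[2]])
        for p in range(1, self.length_ - 2):
            cell = self.triples_[p][s[p], s[p + 1]]
            lp += np.log(cell[s[p + 2]] / cell.sum())
        return float(lp)

    def log_background(self, seq: str) -> float:
        s = encode_sequence(seq, self.length_)
        return float(np.log(self.background_[np.arange(self.length_), s]).sum())

    def score_sequence(self, seq: str) -> float:
        """log2 odds of the sequence under the model versus the background."""
        return (self.log_prob(seq) - self.log_background(seq)) / np.log(2.0)

    def transform(self, X) -> np.ndarray:
        return np.array([self.score_sequence(s) for s in X])

    @property
    def score_range(self):
        return None  # log-odds ratio: no finite range

    def distribution(self) -> np.ndarray:
        """Full probability vector over all 4^L sequences (L <= 8 only)."""
        check_is_fitted(self, "singles_")
        if self.length_ > 8:
            raise ValueError("full enumeration limited to L <= 8")
        from itertools import product

        seqs = ["".join(t) for t in product(ALPHABET, repeat=self.length_)]
        return np.exp([self.log_prob(s) for s in seqs])

    def to_json(self) -> str:
        check_is_fitted(self, "singles_")
        d = {
            "format": "scsnv-maxent",
            "version": 1,
            "site_kind": self.site_kind,
            "constraint_order": self.constraint_order,
            "pseudocount": self.pseudocount,
            "background": self.background_.tolist(),
            "singles": self.singles_.tolist(),
        }
        if self.constraint_order >= 2:
            d["pairs"] = self.pairs_.tolist()
        if self.constraint_order == 3:
            d["triples"] = self.triples_.tolist()
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "MaxEntSpliceModel":
        d = json.loads(text)
        if d.get("format") != "scsnv-maxent":
            raise ValueError("not a scsnv MaxEnt model file")
        model = cls(
            site_kind=d["site_kind"],
            constraint_order=d["constraint_order"],
            pseudocount=d["pseudocount"],
        )
        model.singles_ = np.asarray(d["singles"], dtype=float)
        model.length_ = model.singles_.shape[0]
        canonical = region_for(d["site_kind"])
        model.region_ = canonical if model.length_ == len(canonical) else None
        model.background_ = np.asarray(d["background"], dtype=float)
        if "pairs" in d:
            model.pairs_ = np.asarray(d["pairs"], dtype=float)
        if "triples" in d:
            model.triples_ = np.asarray(d["triples"], dtype=float)
        model._check_marginals()
        return model


# -- thin functional wrappers ----------------------------------------------


def train_pwm(site_sequences, region: RegionDefinition, pseudocount: float = 0.5):
    return PwmSpliceModel(region.site_kind, pseudocount).fit(site_sequences)


def score_pwm(model: PwmSpliceModel, seq: str) -> float:
    return model.score_sequence(seq)


def train_maxent(
    site_sequences,
    region: RegionDefinition,
    constraint_order: int = 2,
    tol: float = 1e-8,
    max_iter: int = 1000,
    pseudocount: float = 0.5,
    background: str = "uniform",
):
    return MaxEntSpliceModel(
        region.site_kind, constraint_order, pseudocount, background, tol, max_iter
    ).fit(site_sequences)


def score_maxent(model: MaxEntSpliceModel, seq: str) -> float:
    return model.score_sequence(seq)
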