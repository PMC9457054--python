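"""Kullback-Leibler information measures for selected/neutral ensemble pairs.

Selection drives the distribution of population states, genotypes and
phenotypes away from what drift and mutation alone would produce.  The
information selection has accumulated is the KL divergence, in bits, between
the distribution under selection (``psi``) and the matched neutral
distribution (``phi``) over the same state space:

    D = sum_u psi(u) * log2(psi(u) / phi(u))

This module provides the discrete-distribution containers and the divergence
machinery (marginal, joint and conditional KL, the chain rule, and the
closed-form divergence generated by the fixation or loss of a single allele)
that the rest of the package builds on.

Conventions
-----------
* All logarithms are base 2; results are in bits.
* ``0 * log(0/q) = 0``: states that selection never produces cost nothing.
* ``p * log(p/0)`` with ``p > 0`` is an absolute-continuity violation and
  raises :class:`AbsoluteContinuityError` rather than returning ``inf`` --
  a neutral process that cannot reach a state the selected process visits
  indicates a modelling bug, not infinite information.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

__all__ = [
    "ProbVector",
    "PairedEnsemble",
    "JointEnsemble",
    "AbsoluteContinuityError",
    "kl_divergence",
    "conditional_kl",
    "joint_kl",
    "fixation_information",
]

#: construction-time renormalisation window: probability sums deviating from 1
#: by less than this are silently renormalised, larger deviations raise.
RENORM_TOL = 1e-9

_LN2 = np.log(2.0)


class AbsoluteContinuityError(ValueError):
    """psi puts mass on a state where phi has none."""


@dataclass(frozen=True)
class ProbVector:
    """A probability distribution over a finite labelled state space.

    Parameters
    ----------
    labels
        Ordered, hashable state identifiers (allele counts, genotypes,
        binned trait values, ...).
    probs
        Nonnegative weights, one per label.  Sums within ``1e-9`` of 1 are
        renormalised on construction; larger deviations raise ``ValueError``.
    """

    labels: tuple
    probs: np.ndarray = field(repr=False)

    def __init__(self, labels: Iterable[Hashable], probs) -> None:
        labels = tuple(labels)
        probs = np.asarray(probs, dtype=float)
        if probs.ndim != 1 or len(labels) != probs.size:
            raise ValueError(
                f"labels ({len(labels)}) and probs ({probs.size}) must align"
            )
        if np.any(probs < 0):
            bad = labels[int(np.argmin(probs))]
            raise ValueError(f"negative probability at label {bad!r}")
        total = probs.sum()
        if abs(total - 1.0) > RENORM_TOL:
            raise ValueError(f"probabilities sum to {total!r}, not 1")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "probs", probs / total)
        self.probs.setflags(write=False)

    def __len__(self) -> int:
        return len(self.labels)

    def prob(self, label: Hashable) -> float:
        return float(self.probs[self.labels.index(label)])

    def to_tsv(self, path) -> None:
        """Serialize as two-column TSV (label, probability)."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label\tprobability\n")
            for lab, p in zip(self.labels, self.probs):
                fh.write(f"{lab}\t{float(p)!r}\n")

    @classmethod
    def from_tsv(cls, path) -> "ProbVector":
        labels, probs = [], []
        with open(path, encoding="utf-8") as fh:
            next(fh)  # header
            for line in fh:
                lab, p = line.rstrip("\n").split("\t")
                labels.append(lab)
                probs.append(float(p))
        return cls(labels, probs)


@dataclass(frozen=True)
class PairedEnsemble:
    """Matched selected/neutral distributions over one labelled space.

    The substrate of every information measure: ``selected`` is the
    distribution under selection (psi), ``neutral`` the matched neutral
    distribution (phi).  Both must be defined over identical labels in
    identical order.  Absolute continuity (phi > 0 wherever psi > 0) is
    checked lazily by :func:`kl_divergence` so that the offending label can
    be named.
    """

    selected: ProbVector
    neutral: ProbVector

    def __post_init__(self) -> None:
        if self.selected.labels != self.neutral.labels:
            raise ValueError("selected and neutral label sets differ")

    @classmethod
    def from_arrays(cls, labels, selected, neutral) -> "PairedEnsemble":
        return cls(ProbVector(labels, selected), ProbVector(labels, neutral))


@dataclass(frozen=True)
class JointEnsemble:
    """Selected and neutral joint distributions over pairs (u, v).

    ``selected`` and ``neutral`` are matrices with rows indexed by
    ``row_labels`` (variable U) and columns by ``col_labels`` (variable V),
    each summing to 1.
    """

    row_labels: tuple
    col_labels: tuple
    selected: np.ndarray = field(repr=False)
    neutral: np.ndarray = field(repr=False)

    def __init__(self, row_labels, col_labels, selected, neutral) -> None:
        row_labels = tuple(row_labels)
        col_labels = tuple(col_labels)
        selected = np.asarray(selected, dtype=float)
        neutral = np.asarray(neutral, dtype=float)
        shape = (len(row_labels), len(col_labels))
        for name, mat in (("selected", selected), ("neutral", neutral)):
            if mat.shape != shape:
                raise ValueError(f"{name} joint has shape {mat.shape}, want {shape}")
            if np.any(mat < 0):
                raise ValueError(f"{name} joint has negative entries")
            total = mat.sum()
            if abs(total - 1.0) > RENORM_TOL:
                raise ValueError(f"{name} joint sums to {total!r}, not 1")
        object.__setattr__(self, "row_labels", row_labels)
        object.__setattr__(self, "col_labels", col_labels)
        object.__setattr__(self, "selected", selected / selected.sum())
        object.__setattr__(self, "neutral", neutral / neutral.sum())
        self.selected.setflags(write=False)
        self.neutral.setflags(write=False)

    def marginal(self, axis: str) -> PairedEnsemble:
        """Marginal paired ensemble over U (``axis='u'``) or V (``axis='v'``)."""
        if axis == "u":
            labels, ax = self.row_labels, 1
        elif axis == "v":
            labels, ax = self.col_labels, 0
        else:
            raise ValueError("axis must be 'u' or 'v'")
        return PairedEnsemble.from_arrays(
            labels, self.selected.sum(axis=ax), self.neutral.sum(axis=ax)
        )

    def check_marginals(
        self, u: PairedEnsemble | None = None, v: PairedEnsemble | None = None,
        tol: float = 1e-10,
    ) -> None:
        """Raise if the joint's marginals disagree with the given marginals."""
        for given, axis in ((u, "u"), (v, "v")):
            if given is None:
                continue
            own = self.marginal(axis)
            if (np.max(np.abs(own.selected.probs - given.selected.probs)) > tol
                    or np.max(np.abs(own.neutral.probs - given.neutral.probs)) > tol):
                raise ValueError(f"joint marginal over {axis!r} inconsistent")


def _kl_bits(psi: np.ndarray, phi: np.ndarray, labels: Sequence | None = None) -> float:
    """Core KL sum in bits with the 0*log0 convention; raises on psi>0, phi=0."""
    psi = np.asarray(psi, dtype=float)
    phi = np.asarray(phi, dtype=float)
    support = psi > 0
    if np.any(phi[support] == 0):
        idx = int(np.flatnonzero(support & (phi == 0))[0])
        name = labels[idx] if labels is not None else idx
        raise AbsoluteContinuityError(
            f"selected distribution has mass {psi[idx]!r} on state {name!r} "
            "that the neutral distribution cannot reach"
        )
    p, q = psi[support], phi[support]
    return float(np.sum(p * (np.log(p) - np.log(q))) / _LN2)


def kl_divergence(pair: PairedEnsemble) -> float:
    """Information D = KL(psi || phi) in bits for a paired ensemble.

    Nonnegative; zero iff the two distributions coincide.
    """
    return _kl_bits(pair.selected.probs, pair.neutral.probs, pair.selected.labels)


def joint_kl(joint: JointEnsemble) -> float:
    """Joint divergence D(U, V) in bits."""
    labels = [(u, v) for u in joint.row_labels for v in joint.col_labels]
    return _kl_bits(joint.selected.ravel(), joint.neutral.ravel(), labels)


def conditional_kl(joint: JointEnsemble, given: str = "u") -> float:
    """Conditional divergence in bits: D(V|U) for ``given='u'``, D(U|V) for 'v'.

    D(V|U) = sum_u psi_U(u) sum_v psi(v|u) log2( psi(v|u) / phi(v|u) ),
    the average over selected states u of the divergence between the selected
    and neutral conditionals.  Conditioning states with zero probability under
    psi contribute nothing; states with psi_U(u) > 0 but phi_U(u) = 0 violate
    absolute continuity and raise.

    Together with the marginal divergences this realises the chain rule
    D(U,V) = D(U) + D(V|U) = D(V) + D(U|V).
    """
    if given == "u":
        sel, neu = joint.selected, joint.neutral
        labels = joint.row_labels
    elif given == "v":
        sel, neu = joint.selected.T, joint.neutral.T
        labels = joint.col_labels
    else:
        raise ValueError("given must be 'u' or 'v'")
    psi_m = sel.sum(axis=1)
    phi_m = neu.sum(axis=1)
    total = 0.0
    for i, pu in enumerate(psi_m):
        if pu == 0.0:
            continue
        if phi_m[i] == 0.0:
            raise AbsoluteContinuityError(
                f"conditioning state {labels[i]!r} has selected mass but no "
                "neutral mass"
            )
        total += pu * _kl_bits(sel[i] / pu, neu[i] / phi_m[i], labels=None)
    return total


def fixation_information(psi_fix: float, N: int) -> float:
    """Information accumulated by the fixation or loss of a single new allele.

    A beneficial allele starting from one copy in a haploid population of size
    ``N`` is ultimately fixed (probability ``psi_fix`` under selection, 1/N
    under neutrality) or lost.  The divergence between the selected and
    neutral fate distributions is

        psi_fix * log2(N * psi_fix)
        + (1 - psi_fix) * log2( N * (1 - psi_fix) / (N - 1) )

    in bits -- exactly the two-point KL of (psi_fix, 1-psi_fix) against
    (1/N, 1-1/N).
    """
    if not 0.0 <= psi_fix <= 1.0:
        raise ValueError(f"psi_fix={psi_fix!r} outside [0, 1]")
    if N < 2:
        raise ValueError(f"N={N!r} must be >= 2")
    total = 0.0
    if psi_fix > 0.0:
        total += psi_fix * np.log2(N * psi_fix)
    if psi_fix < 1.0:
        total += (1.0 - psi_fix) * np.log2(N * (1.0 - psi_fix) / (N - 1.0))
    return float(total)
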