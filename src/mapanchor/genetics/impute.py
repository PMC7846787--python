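"""Parental-haplotype assignment: a 2-state Viterbi HMM per sample per contig.

States are the two parents. The transition probability between adjacent
markers is the per-marker switch probability; emissions are fixed:
matching homozygote ``1 - error``, opposite homozygote ``error``,
heterozygote a small flat probability in both states, missing
uninformative. Output labels fill missing entries, so the result has no
missing data.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from mapanchor.config import PipelineConfig
from mapanchor.genotypes import (
    CALL_A,
    CALL_B,
    CALL_H,
    CALL_MISSING,
    EmptyMatrixError,
    MarkerGenotypeMatrix,
    ParentalHaplotypeMatrix,
)

logger = logging.getLogger(__name__)


def polarize_by_parents(m: MarkerGenotypeMatrix) -> tuple[MarkerGenotypeMatrix, int]:
    """Recode calls so A is the first parent's allele; drop unusable markers.

    A marker is kept only when both parent calls are homozygous and
    opposite. Returns the polarized matrix (parents removed from the
    sample axis) and the number of dropped markers.
    """
    if m.parents is None:
        raise ValueError("parents must be designated")
    ia = m.sample_index(m.parents[0])
    ib = m.sample_index(m.parents[1])
    pa = m.calls[:, ia]
    pb = m.calls[:, ib]
    usable = ((pa == CALL_A) & (pb == CALL_B)) | ((pa == CALL_B) & (pb == CALL_A))
    n_dropped = int((~usable).sum())
    if not usable.any():
        raise EmptyMatrixError("no marker has informative, opposite parent calls")
    if n_dropped:
        logger.warning("dropped %d markers with unusable parent calls", n_dropped)
    flip = (pa == CALL_B)[:, None]
    calls = m.calls.copy()
    a_mask = calls == CALL_A
    b_mask = calls == CALL_B
    calls[flip & a_mask] = CALL_B
    calls[flip & b_mask] = CALL_A
    keep_cols = m.non_parent_columns()
    samples = [s for s, k in zip(m.samples, keep_cols) if k]
    idx = np.flatnonzero(usable)
    return (
        MarkerGenotypeMatrix(
            markers=m.markers.iloc[idx].reset_index(drop=True),
            samples=samples,
            calls=calls[np.ix_(idx, np.flatnonzero(keep_cols))],
            gq=m.gq[np.ix_(idx, np.flatnonzero(keep_cols))],
            parents=None,
        ),
        n_dropped,
    )


def _emission_log(config: PipelineConfig) -> np.ndarray:
    """log P(obs | state) as a (4 obs codes, 2 states) array."""
    e = config.hmm_error_rate
    h = config.hmm_het_emission
    em = np.empty((4, 2))
    em[CALL_A] = (math.log(1 - e), math.log(e))
    em[CALL_B] = (math.log(e), math.log(1 - e))
    em[CALL_H] = (math.log(h), math.log(h))
    em[CALL_MISSING] = (0.0, 0.0)
    return em


def path_log_probability(
    calls: np.ndarray, labels: np.ndarray, config: PipelineConfig
) -> float:
    """Joint log probability of a label path given observed calls.

    Uniform initial distribution over the two states. Shared model
    definition for both the Viterbi implementation and enumeration-based
    checks.
    """
    em = _emission_log(config)
    c = math.log(config.hmm_switch_prob)
    s = math.log(1 - config.hmm_switch_prob)
    lp = math.log(0.5) + em[calls[0], labels[0]]
    for k in range(1, len(calls)):
        lp += (c if labels[k] != labels[k - 1] else s) + em[calls[k], labels[k]]
    return lp


def _viterbi_block(calls: np.ndarray, config: PipelineConfig) -> np.ndarray:
    """Viterbi paths for a (n_markers, n_samples) block of one contig.

    Vectorized over samples; ties prefer staying in the current state and
    state A at the start.
    """
    em = _emission_log(config)
    log_stay = math.log(1 - config.hmm_switch_prob)
    log_switch = math.log(config.hmm_switch_prob)
    n_m, n_s = calls.shape
    delta = em[calls[0]] + math.log(0.5)  # (n_s, 2)
    back = np.empty((n_m, n_s, 2), dtype=np.int8)
    for k in range(1, n_m):
        # score[j, prev, cur]
        stay = delta + log_stay  # arriving without switching
        switch = delta[:, ::-1] + log_switch
        choose_switch = switch > stay  # strict: ties keep previous state
        best = np.where(choose_switch, switch, stay)
        back[k, :, 0] = np.where(choose_switch[:, 0], 1, 0)
        back[k, :, 1] = np.where(choose_switch[:, 1], 0, 1)
        delta = best + em[calls[k]]
    labels = np.empty((n_m, n_s), dtype=np.int8)
    last = np.where(delta[:, 1] > delta[:, 0], 1, 0)  # tie -> state A
    labels[-1] = last
    for k in range(n_m - 1, 0, -1):
        last = back[k, np.arange(n_s), last]
        labels[k - 1] = last
    return labels


def _majority_labels(calls: np.ndarray) -> np.ndarray:
    """Per-sample majority of homozygote calls; ties and no-information -> A."""
    n_a = (calls == CALL_A).sum(axis=0)
    n_b = (calls == CALL_B).sum(axis=0)
    maj = np.where(n_b > n_a, CALL_B, CALL_A).astype(np.int8)
    return np.broadcast_to(maj, calls.shape).copy()


def assign_parental_haplotypes(
    m: MarkerGenotypeMatrix, config: PipelineConfig
) -> ParentalHaplotypeMatrix:
    """Impute parent-of-origin labels for every marker of every sample.

    ``m`` may still carry its designated parents (they are polarized away)
    or already be polarized (``parents is None``), in which case calls are
    assumed A-coded against the first parent.
    """
    if m.parents is not None:
        m, _ = polarize_by_parents(m)
    labels = np.empty_like(m.calls)
    low_info: set[str] = set()
    for contig, idx in m.contig_marker_index().items():
        block = m.calls[idx]
        informative = int(((block == CALL_A) | (block == CALL_B)).any(axis=1).sum())
        if informative < 2:
            labels[idx] = _majority_labels(block)
            low_info.add(contig)
        else:
            labels[idx] = _viterbi_block(block, config)
    return ParentalHaplotypeMatrix(
        markers=m.markers,
        samples=list(m.samples),
        labels=labels,
        low_information_contigs=low_info,
    )
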