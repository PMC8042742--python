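"""Founder-haplotype reconstruction for multiparent RILs.

Each RIL genome is a mosaic of founder haplotypes with residual heterozygous
regions left over from finite selfing. The hidden state at a marker is the
unordered founder pair carried by the two homologs: for a four-founder
subpopulation, 4 homozygous + 6 heterozygous = 10 states. Decoding uses a
scaled forward-backward pass over noisy biallelic dosage calls (0/1/2 with
missing codes), with

* emission: each of the two allele observations flips independently with
  error rate ``epsilon`` (so an uninformative ``epsilon = 0.5`` collapses
  the emission to the same distribution for every state),
* transition over an inter-marker interval of d Morgans: stay with
  probability exp(-k d), otherwise jump to a state drawn from the prior
  (``k`` scales the expected number of state switches; the jump kernel
  keeps the homozygosity-enriched prior stationary along the chromosome),
* prior: homozygous states share weight 1 - h, heterozygous states share
  the residual-heterozygosity weight h (default the F6 single-seed-descent
  expectation h = 2^-5).

Maximum-a-posteriori states are smoothed into haplotype blocks whose
boundaries sit at the midpoint between the two markers flanking a state
switch; runs shorter than ``min_markers`` are absorbed into the flanking
run with higher adjacent posterior support.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeMap
from .sim_ril import MISSING, SimulatedIndividual

__all__ = [
    "enumerate_states",
    "HmmParams",
    "state_prior",
    "transition_matrix",
    "emission_probabilities",
    "decode_posteriors",
    "call_blocks",
    "decode_individual",
]

State = tuple[str, str]


def enumerate_states(founders) -> list[State]:
    """All unordered founder pairs, homozygous included, in canonical
    (sorted) order.

    For n founders this yields C(n, 2) + n states (10 for a quadruple).
    """
    founders = list(founders)
    if len(set(founders)) != len(founders):
        raise ValueError("duplicate founders")
    if len(founders) < 2:
        raise ValueError("need at least two founders")
    f = sorted(founders)
    return sorted(
        [(a, a) for a in f]
        + [tuple(sorted(p)) for p in itertools.combinations(f, 2)]
    )


@dataclass(frozen=True)
class HmmParams:
    """Decoding parameters.

    error_rate
        Per-allele genotyping error epsilon, in (0, 0.5].
    switch_scale
        k in the stay probability exp(-k d); 1.0 means one expected state
        switch per Morgan.
    residual_het
        Prior weight h on the heterozygous states jointly; default is the
        F6 expectation 2**-5.
    """

    error_rate: float = 0.005
    switch_scale: float = 1.0
    residual_het: float = 2.0 ** -5

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate <= 0.5:
            raise ValueError("error_rate must be in (0, 0.5]")
        if self.switch_scale < 0:
            raise ValueError("switch_scale must be non-negative")
        if not 0.0 <= self.residual_het < 1.0:
            raise ValueError("residual_het must be in [0, 1)")


def state_prior(states: list[State], params: HmmParams) -> np.ndarray:
    hom = np.array([s[0] == s[1] for s in states])
    n_hom, n_het = hom.sum(), (~hom).sum()
    prior = np.empty(len(states))
    if n_het == 0:
        prior[:] = 1.0 / n_hom
        return prior
    prior[hom] = (1.0 - params.residual_het) / n_hom
    prior[~hom] = params.residual_het / n_het
    return prior


def transition_matrix(
    d_morgans: float, prior: np.ndarray, switch_scale: float
) -> np.ndarray:
    """Transition matrix over an interval of ``d_morgans``: stay with
    probability exp(-k d), otherwise jump to a state drawn from the prior
    (so the prior is the chain's stationary distribution)."""
    stay = float(np.exp(-switch_scale * max(d_morgans, 0.0)))
    t = (1.0 - stay) * np.tile(prior, (len(prior), 1))
    t[np.diag_indices_from(t)] += stay
    return t


def _allele_flip_kernel(eps: float) -> np.ndarray:
    """P(observed dosage | true dosage), per-allele flip error model."""
    q = 1.0 - eps
    return np.array(
        [
            [q * q, 2 * eps * q, eps * eps],
            [eps * q, q * q + eps * eps, eps * q],
            [eps * eps, 2 * eps * q, q * q],
        ]
    )


def emission_probabilities(
    observations: np.ndarray,
    founder_alleles: dict[str, np.ndarray],
    states: list[State],
    params: HmmParams,
) -> np.ndarray:
    """Emission likelihood matrix (markers x states).

    Missing observations contribute likelihood 1 in every state.
    """
    obs = np.asarray(observations)
    m = obs.shape[0]
    kernel = _allele_flip_kernel(params.error_rate)
    out = np.ones((m, len(states)))
    valid = obs != MISSING
    if not valid.any():
        raise ValueError("observation vector is entirely missing")
    for j, (f1, f2) in enumerate(states):
        true_dosage = founder_alleles[f1] + founder_alleles[f2]
        out[valid, j] = kernel[true_dosage[valid], obs[valid]]
    return out


def decode_posteriors(
    observations: np.ndarray,
    founder_alleles: dict[str, np.ndarray],
    positions_morgans: np.ndarray,
    states: list[State],
    params: HmmParams,
) -> tuple[np.ndarray, float]:
    """Scaled forward-backward posterior decoding.

    Parameters
    ----------
    observations
        Dosage calls (0/1/2, :data:`~dupincompat.sim_ril.MISSING` allowed)
        at the markers of one chromosome.
    founder_alleles
        Founder -> 0/1 allele vector aligned with the markers.
    positions_morgans
        Genetic positions of the markers (Morgans), non-decreasing.

    Returns
    -------
    posteriors, log_likelihood
        ``posteriors`` is (markers x states), each row summing to 1.
    """
    emis = emission_probabilities(observations, founder_alleles, states, params)
    m, n = emis.shape
    prior = state_prior(states, params)
    d = np.diff(np.asarray(positions_morgans, dtype=float))
    if np.any(d < 0):
        raise ValueError("marker genetic positions must be non-decreasing")

    alpha = np.empty((m, n))
    scale = np.empty(m)
    a = prior * emis[0]
    scale[0] = a.sum()
    alpha[0] = a / scale[0]
    for t in range(1, m):
        trans = transition_matrix(d[t - 1], prior, params.switch_scale)
        a = (alpha[t - 1] @ trans) * emis[t]
        scale[t] = a.sum()
        alpha[t] = a / scale[t]

    beta = np.empty((m, n))
    beta[m - 1] = 1.0
    for t in range(m - 2, -1, -1):
        trans = transition_matrix(d[t], prior, params.switch_scale)
        b = trans @ (emis[t + 1] * beta[t + 1])
        beta[t] = b / scale[t + 1]

    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    loglik = float(np.log(scale).sum())
    return post, loglik


def backward_loglikelihood(
    observations: np.ndarray,
    founder_alleles: dict[str, np.ndarray],
    positions_morgans: np.ndarray,
    states: list[State],
    params: HmmParams,
) -> float:
    """Likelihood computed from an independently scaled backward pass
    (used to cross-check the forward pass)."""
    emis = emission_probabilities(observations, founder_alleles, states, params)
    m, n = emis.shape
    prior = state_prior(states, params)
    d = np.diff(np.asarray(positions_morgans, dtype=float))
    beta = np.ones(n)
    log_c = 0.0
    for t in range(m - 2, -1, -1):
        trans = transition_matrix(d[t], prior, params.switch_scale)
        beta = trans @ (emis[t + 1] * beta)
        c = beta.sum()
        beta /= c
        log_c += np.log(c)
    return float(np.log((prior * emis[0] * beta).sum()) + log_c)


def _runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index runs of constant value."""
    out = []
    start = 0
    for i in range(1, len(values)):
        if values[i] != values[i - 1]:
            out.append((start, i))
            start = i
    out.append((start, len(values)))
    return out


def call_blocks(
    posteriors: np.ndarray,
    states: list[State],
    positions_bp: np.ndarray,
    chrom: str,
    chrom_length: int,
    min_posterior: float = 0.0,
    min_markers: int = 1,
) -> pd.DataFrame:
    """Smooth per-marker MAP states into haplotype blocks.

    Markers whose MAP posterior falls below ``min_posterior`` inherit the
    state of the nearest confident marker to the left (to the right at the
    chromosome start). MAP ties break to the lowest canonical state index.
    Block boundaries are placed at the midpoint between the two markers
    flanking a state switch (BED convention, 0-based half-open).

    Returns a DataFrame with columns chrom, start, end, state,
    mean_posterior; breakpoints are the internal block boundaries.
    """
    post = np.asarray(posteriors)
    positions = np.asarray(positions_bp)
    map_states = post.argmax(axis=1)
    confident = post.max(axis=1) >= min_posterior
    if confident.any():
        idx = np.where(confident, np.arange(len(map_states)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(confident)
        idx[idx < 0] = first
        map_states = map_states[idx]

    runs = _runs(map_states)
    # absorb short runs into the flanking run with higher adjacent posterior
    while len(runs) > 1:
        lengths = [b - a for a, b in runs]
        short = [i for i, L in enumerate(lengths) if L < min_markers]
        if not short:
            break
        i = min(short, key=lambda j: lengths[j])
        a, b = runs[i]
        left_state = map_states[runs[i - 1][0]] if i > 0 else None
        right_state = map_states[runs[i + 1][0]] if i < len(runs) - 1 else None
        if left_state is None:
            winner = right_state
        elif right_state is None:
            winner = left_state
        else:
            left_support = post[a:b, left_state].mean()
            right_support = post[a:b, right_state].mean()
            winner = left_state if left_support >= right_support else right_state
        map_states[a:b] = winner
        runs = _runs(map_states)

    rows = []
    for k, (a, b) in enumerate(runs):
        start = 0 if k == 0 else (positions[a - 1] + positions[a]) // 2
        end = (
            chrom_length
            if k == len(runs) - 1
            else (positions[b - 1] + positions[b]) // 2
        )
        s = map_states[a]
        rows.append(
            {
                "chrom": chrom,
                "start": int(start),
                "end": int(end),
                "state": "|".join(states[s]),
                "mean_posterior": float(post[a:b, s].mean()),
            }
        )
    return pd.DataFrame(rows)


def decode_individual(
    individual: SimulatedIndividual,
    genome: GenomeMap,
    founder_alleles: dict[str, dict[str, np.ndarray]],
    founders,
    params: HmmParams | None = None,
    min_posterior: float = 0.0,
    min_markers: int = 1,
) -> pd.DataFrame:
    """Decode every chromosome of one RIL and return its block set."""
    params = params or HmmParams()
    states = enumerate_states(founders)
    blocks = []
    for c in genome.chromosomes:
        obs = individual.observed[c.id]
        alleles = {f: founder_alleles[f][c.id] for f in founders}
        post, _ = decode_posteriors(
            obs, alleles, genome.marker_morgans(c.id), states, params
        )
        blocks.append(
            call_blocks(
                post,
                states,
                genome.markers[c.id],
                c.id,
                c.length_bp,
                min_posterior=min_posterior,
                min_markers=min_markers,
            )
        )
    return pd.concat(blocks, ignore_index=True)
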