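"""Positional amino-acid usage bias statistics.

Three related analyses live here:

* ``position_bias_table`` — per-residue signed HGT scores comparing usage at
  one position (typically position 2) against the pooled proteome background
  (Fmean).
* ``aspecificity_score`` — a sliding-window check that a position-2 bias is
  really specific to position 2 and not a generic compositional feature of
  the protein's first few hundred residues.
* ``positional_hgt_matrix`` — residue x position matrix of signed HGT scores
  for a protein subset against a reference collection, position by position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .hypergeom import hgt_score
from .proteome import (RESIDUES, BackgroundFrequencies, PositionProfile,
                       ProteinRecord, position_profile)

__all__ = [
    "BiasResult", "position_bias_table", "f2ref", "aspecificity_score",
    "aspecificity_table", "positional_hgt_matrix",
]


@dataclass
class BiasResult:
    """One scored (residue, position) usage bias."""

    residue: str
    position: int
    f_obs: float
    f_ref: float
    log2_ratio: float
    hgt: float
    k: int
    n: int
    K: int
    N: int
    aspecificity: float | None = None


def _log2_ratio(f_obs: float, f_ref: float) -> float:
    if f_obs == 0.0:
        return -math.inf
    if f_ref == 0.0:
        return math.inf
    return math.log2(f_obs / f_ref)


def position_bias_table(profile: PositionProfile,
                        background: BackgroundFrequencies,
                        position: int = 2) -> pd.DataFrame:
    """Per-residue usage bias at one position versus the proteome background.

    The reference is materialised as a hypergeometric draw from the pooled
    residue counts of the whole proteome: N = total pooled residues, K = the
    residue's pooled count, n = proteins contributing at ``position``, k =
    the observed count there.  Returns a DataFrame indexed by residue with
    columns ``f_obs, f_ref, log2_ratio, hgt, k, n, K, N``.
    """
    if not 1 <= position <= profile.max_position:
        raise ValueError(f"position {position} outside profile range")
    n = int(profile.n_at_position[position - 1])
    if n == 0:
        raise ValueError(f"no protein contributes at position {position}")
    N = background.total
    rows = []
    for residue in RESIDUES:
        k = profile.count_at(position, residue)
        K = background.counts[residue]
        f_obs = k / n
        f_ref = K / N
        rows.append(BiasResult(
            residue=residue, position=position, f_obs=f_obs, f_ref=f_ref,
            log2_ratio=_log2_ratio(f_obs, f_ref),
            hgt=hgt_score(k, K, n, N), k=k, n=n, K=K, N=N))
    df = pd.DataFrame([vars(r) for r in rows]).set_index("residue")
    return df.drop(columns=["aspecificity"])


def f2ref(f2: float, fmean: float) -> float:
    """Reference frequency for the aspecificity test: 10% below the
    position-2 frequency for over-represented residues, 10% above it for
    under-represented ones."""
    return 0.9 * f2 if f2 > fmean else 1.1 * f2


def aspecificity_score(f2: float, fmean: float,
                       position_freqs: Sequence[float],
                       window: int = 100, span: int = 500,
                       start_position: int = 3) -> float:
    """Maximum local aspecificity over sliding windows, as a percentage.

    ``position_freqs[p-1]`` is the residue's frequency at 1-based position
    ``p`` (NaN where no protein is long enough).  Windows of ``window``
    consecutive positions slide one position at a time over
    ``start_position .. span``; within each window the local score is the
    percentage of valid positions whose frequency crosses the reference
    ``f2ref`` (above it when F2 > Fmean, at or below it otherwise).  The
    retained score is the maximum over windows — 0% means the position-2
    bias is never echoed anywhere else, i.e. the bias is fully specific.

    Positions 1 and 2 are excluded by default: position 1 is the invariant
    iMet and position 2 is the position under test.
    """
    if window > span:
        raise ValueError("window exceeds span")
    freqs = np.asarray(position_freqs, dtype=float)
    if len(freqs) < span:
        raise ValueError(f"need frequencies for {span} positions, "
                         f"got {len(freqs)}")
    ref = f2ref(f2, fmean)
    region = freqs[start_position - 1:span]
    valid = ~np.isnan(region)
    if not valid.any():
        raise ValueError("no valid positions in the analysis span")
    if f2 > fmean:
        crossing = valid & (region > ref)
    else:
        crossing = valid & (region <= ref)
    best = 0.0
    for start in range(0, len(region) - window + 1):
        n_valid = int(valid[start:start + window].sum())
        if n_valid == 0:
            continue
        n_cross = int(crossing[start:start + window].sum())
        best = max(best, 100.0 * n_cross / n_valid)
    return best


def aspecificity_table(proteins: Sequence[ProteinRecord],
                       background: BackgroundFrequencies,
                       window: int = 100, span: int = 500) -> pd.Series:
    """Aspecificity score for all 20 residues of a protein collection.

    Builds the positional frequency profile over the first ``span``
    positions once and scores every residue's position-2 bias against it.
    """
    profile = position_profile(proteins, max_position=span)
    freq = profile.freq  # (span, 20)
    n2 = profile.n_at_position[1]
    if n2 == 0:
        raise ValueError("no protein contributes at position 2")
    scores = {}
    for i, residue in enumerate(RESIDUES):
        f2 = profile.counts[1, i] / n2
        scores[residue] = aspecificity_score(
            f2, background[residue], freq[:, i], window=window, span=span)
    return pd.Series(scores, name="aspecificity")


def positional_hgt_matrix(subset: Sequence[ProteinRecord],
                          reference: Sequence[ProteinRecord],
                          positions: Sequence[int]) -> pd.DataFrame:
    """Residue x position matrix of signed HGT scores for a protein subset.

    At each position p the urn is the reference collection restricted to
    proteins with a canonical residue at p (N of which K carry residue r);
    the draw is the subset restricted the same way (n, of which k carry r).
    Cells are signed HGT scores; a subset identical to the reference scores
    0 everywhere.
    """
    positions = list(positions)
    if not positions:
        raise ValueError("empty position range")
    ref_accessions = {r.accession for r in reference}
    missing = [s.accession for s in subset
               if s.accession not in ref_accessions]
    if missing:
        raise ValueError(
            f"subset proteins absent from the reference: {missing[:5]}"
            + ("..." if len(missing) > 5 else ""))
    max_pos = max(positions)
    ref_profile = position_profile(reference, max_position=max_pos)
    sub_profile = position_profile(subset, max_position=max_pos)
    matrix = pd.DataFrame(0.0, index=list(RESIDUES), columns=positions)
    for pos in positions:
        N = int(ref_profile.n_at_position[pos - 1])
        n = int(sub_profile.n_at_position[pos - 1])
        if n == 0 or N == 0:
            matrix[pos] = np.nan
            continue
        for residue in RESIDUES:
            K = ref_profile.count_at(pos, residue)
            k = sub_profile.count_at(pos, residue)
            matrix.loc[residue, pos] = hgt_score(k, K, n, N)
    return matrix
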