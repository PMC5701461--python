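"""Sliding-window percent identity between two aligned sequences.

The scan mirrors the classic DnaSP-style conservation profile used to
visualize gene-conversion tracts between paralogs: columns gapped in either
sequence are stripped, identity is computed in overlapping windows
(default 20 bp, step 1 bp), and maximal runs of high-identity windows are
segmented into candidate converted regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import Alignment, RegionMap, GAPLIKE


@dataclass
class IdentityTrack:
    """Per-window identity on the gap-stripped frame.

    window_starts index into the stripped frame; column_map maps stripped
    positions back to original alignment columns.
    """

    window: int
    step: int
    values: np.ndarray          # identity in [0,1], one per window
    window_starts: np.ndarray   # stripped-frame start of each window
    column_map: np.ndarray      # stripped position -> alignment column


def _pair_arrays(aln: Alignment, count_gaps_as_mismatch: bool):
    if aln.n_sequences != 2:
        raise ValueError(f"identity scan needs exactly 2 sequences, got {aln.n_sequences}")
    a = np.array(list(aln.rows[0]), dtype="U1")
    b = np.array(list(aln.rows[1]), dtype="U1")
    gappy = np.isin(a, list(GAPLIKE)) | np.isin(b, list(GAPLIKE))
    if count_gaps_as_mismatch:
        keep = np.ones(a.size, dtype=bool)
        match = (a == b) & ~gappy
    else:
        keep = ~gappy
        match = (a == b)
    return match[keep], np.flatnonzero(keep)


def sliding_identity(aln: Alignment, window: int = 20, step: int = 1,
                     count_gaps_as_mismatch: bool = False) -> IdentityTrack:
    """Windowed identity profile of a two-row alignment.

    Gapped columns are removed before windowing by default, so windows span
    `window` comparable sites each.
    """
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    match, column_map = _pair_arrays(aln, count_gaps_as_mismatch)
    usable = match.size
    if window > usable:
        raise ValueError(f"window {window} exceeds usable length {usable}")
    csum = np.concatenate([[0], np.cumsum(match)])
    starts = np.arange(0, usable - window + 1, step)
    values = (csum[starts + window] - csum[starts]) / window
    return IdentityTrack(window, step, values, starts, column_map)


def segment_regions(track: IdentityTrack, threshold: float = 0.97,
                    min_len: int = 500, prefix: str = "hi") -> RegionMap:
    """Maximal runs of windows with identity >= threshold, as labeled intervals.

    Runs separated by gaps shorter than the window are merged; merged runs
    shorter than min_len (bp, stripped frame) are dropped.  Intervals are
    reported on the stripped frame: [first window start, last window end).
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    if min_len < track.window:
        raise ValueError("min_len must be >= window")
    hi = track.values >= threshold
    if track.values.size == 0 or not hi.any():
        return RegionMap([])
    # runs of consecutive hi windows
    runs = []
    idx = np.flatnonzero(hi)
    run_start = idx[0]
    prev = idx[0]
    for i in idx[1:]:
        if i != prev + 1:
            runs.append((run_start, prev))
            run_start = i
        prev = i
    runs.append((run_start, prev))
    # to bp intervals on the stripped frame
    intervals = [
        (int(track.window_starts[a]), int(track.window_starts[b]) + track.window)
        for a, b in runs
    ]
    # merge across gaps shorter than one window
    merged = [intervals[0]]
    for s, e in intervals[1:]:
        ps, pe = merged[-1]
        if s - pe < track.window:
            merged[-1] = (ps, e)
        else:
            merged.append((s, e))
    kept = [(s, e) for s, e in merged if e - s >= min_len]
    return RegionMap([(f"{prefix}_{i + 1}", s, e) for i, (s, e) in enumerate(kept)])


def mean_identity(aln: Alignment, regions: RegionMap, label: str,
                  count_gaps_as_mismatch: bool = False) -> float:
    """Ungapped percent identity over all columns of the labeled region."""
    regions.validate_against(aln)
    cols = regions.columns(label)
    sub = aln.take_columns(cols)
    a = np.array(list(sub.rows[0]), dtype="U1")
    b = np.array(list(sub.rows[1]), dtype="U1")
    gappy = np.isin(a, list(GAPLIKE)) | np.isin(b, list(GAPLIKE))
    if count_gaps_as_mismatch:
        compared = a.size
        matches = int(((a == b) & ~gappy).sum())
    else:
        compared = int((~gappy).sum())
        matches = int((a == b)[~gappy].sum())
    if compared == 0:
        raise ValueError(f"no comparable columns in region {label!r}")
    return 100.0 * matches / compared
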