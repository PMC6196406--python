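"""Per-site substitution profiles, sliding windows and cumulative curves.

A :class:`SiteProfile` is the exact per-site tally of classified events; a
:class:`WindowSeries` holds window means of the four categories together
with dS, dN and dN/dS; :func:`cumulative_series` gives running totals (Kt)
along the sequence. Windows and cumulative curves are cheap views over the
profile, so window and step can be changed freely without touching the
event list.

dN and dS here are raw substitution counts — dS = As + Bs and
dN = Aa + Ba per window — NOT per-site-normalized rates: there is no
NG86/GY-style counting of synonymous and nonsynonymous sites. The ratio is
therefore a descriptive profile statistic, comparable along the sequence
but not numerically comparable to model-based dN/dS estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import CATEGORIES, SubstitutionEvent, codon_position
from .errors import SiteOutOfRangeError, WindowError

#: the twelve directed base changes, transitions first.
CHANGE_TYPES = (
    "A>G", "G>A", "C>T", "T>C",
    "A>C", "C>A", "A>T", "T>A", "G>C", "C>G", "G>T", "T>G",
)


@dataclass(frozen=True)
class SiteProfile:
    """Exact per-site counts of classified substitutions.

    Arrays are indexed 0..length-1 for sites 1..length. ``type_by_position``
    counts each directed base change per codon position (rows =
    CHANGE_TYPES, columns = positions 1..3).
    """

    length: int
    counts: dict[str, np.ndarray]  # keys As, Bs, Aa, Ba
    ts: np.ndarray
    tv: np.ndarray
    type_by_position: pd.DataFrame

    @property
    def total_events(self) -> int:
        return int(sum(arr.sum() for arr in self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        """Per-site table with 1-based ``site`` and ``codon_position``."""
        sites = np.arange(1, self.length + 1)
        data = {"site": sites, "codon_position": (sites - 1) % 3 + 1}
        data.update({c: self.counts[c] for c in CATEGORIES})
        data["Ts"] = self.ts
        data["Tv"] = self.tv
        return pd.DataFrame(data)


def site_counts(
    events: list[SubstitutionEvent], length: int
) -> SiteProfile:
    """Tally classified events per site, category and change type."""
    counts = {c: np.zeros(length, dtype=int) for c in CATEGORIES}
    ts = np.zeros(length, dtype=int)
    tv = np.zeros(length, dtype=int)
    tbp = pd.DataFrame(
        0, index=list(CHANGE_TYPES), columns=[1, 2, 3], dtype=int
    )
    for ev in events:
        if not 1 <= ev.site <= length:
            raise SiteOutOfRangeError(
                f"event at site {ev.site} outside alignment of length {length}"
            )
        idx = ev.site - 1
        counts[ev.category][idx] += 1
        if ev.mutation_class == "Ts":
            ts[idx] += 1
        else:
            tv[idx] += 1
        tbp.loc[f"{ev.from_base}>{ev.to_base}", codon_position(ev.site)] += 1
    return SiteProfile(
        length=length, counts=counts, ts=ts, tv=tv, type_by_position=tbp
    )


@dataclass(frozen=True)
class WindowSeries:
    """Window means of the four categories plus dS, dN and dN/dS.

    ``ratio`` holds NaN where a window has dS = 0 (the undefined marker);
    it is never +inf.
    """

    window: int
    step: int
    window_starts: np.ndarray  # 1-based
    means: dict[str, np.ndarray]
    ds: np.ndarray  # window mean of As+Bs
    dn: np.ndarray  # window mean of Aa+Ba
    ratio: np.ndarray  # dN/dS, NaN where dS == 0

    @property
    def n_windows(self) -> int:
        return len(self.window_starts)

    def to_frame(self) -> pd.DataFrame:
        data = {"window_start": self.window_starts,
                "window_end": self.window_starts + self.window - 1}
        data.update({c: self.means[c] for c in CATEGORIES})
        data["dS"] = self.ds
        data["dN"] = self.dn
        data["dN/dS"] = self.ratio
        return pd.DataFrame(data)


def sliding_windows(
    profile: SiteProfile, window: int = 90, step: int = 9
) -> WindowSeries:
    """Average the per-site profile over sliding windows.

    Windows start at 1, 1+step, ... while they fit entirely inside the
    alignment; a trailing partial window is dropped so that all window
    means average the same number of sites. Defaults (90 nt window, 9 nt
    step — 30 codons shifted by 3) suit genome-scale coding sequences.
    """
    if window < 3 or window > profile.length:
        raise WindowError(
            f"window must satisfy 3 <= window <= length "
            f"({window} vs length {profile.length})"
        )
    if step < 1:
        raise WindowError(f"step must be >= 1, got {step}")
    starts = np.arange(1, profile.length - window + 2, step)
    means: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        cumsum = np.concatenate(([0], np.cumsum(profile.counts[cat])))
        sums = cumsum[starts - 1 + window] - cumsum[starts - 1]
        means[cat] = sums / window
    ds = means["As"] + means["Bs"]
    dn = means["Aa"] + means["Ba"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(ds > 0, dn / np.where(ds > 0, ds, 1.0), np.nan)
    return WindowSeries(
        window=window, step=step, window_starts=starts,
        means=means, ds=ds, dn=dn, ratio=ratio,
    )


def dn_ds(series: WindowSeries) -> np.ndarray:
    """Per-window dN/dS ratio; NaN marks windows where dS = 0."""
    return series.ratio


@dataclass(frozen=True)
class CumulativeSeries:
    """Running totals of As, Bs, Aa, Ba and Kt at step positions."""

    step: int
    positions: np.ndarray  # 1-based evaluation points, last = length
    totals: dict[str, np.ndarray]
    kt: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        data = {"position": self.positions}
        data.update({c: self.totals[c] for c in CATEGORIES})
        data["Kt"] = self.kt
        return pd.DataFrame(data)


def cumulative_series(profile: SiteProfile, step: int = 9) -> CumulativeSeries:
    """Cumulative category counts along the sequence in step-sized strides.

    Evaluation points are step, 2*step, ...; the final point is always the
    alignment end so the last Kt value equals the total event count.
    """
    if step < 1:
        raise WindowError(f"step must be >= 1, got {step}")
    positions = np.arange(step, profile.length + 1, step)
    if len(positions) == 0 or positions[-1] != profile.length:
        positions = np.concatenate((positions, [profile.length]))
    totals: dict[str, np.ndarray] = {}
    for cat in CATEGORIES:
        cumsum = np.cumsum(profile.counts[cat])
        totals[cat] = cumsum[positions - 1]
    kt = sum(totals[c] for c in CATEGORIES)
    return CumulativeSeries(step=step, positions=positions,
                            totals=totals, kt=kt)
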