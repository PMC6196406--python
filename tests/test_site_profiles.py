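"""Per-site tallies, sliding windows, dN/dS and cumulative curves."""

import numpy as np
import pytest

from subpatterns import (
    build_events,
    cumulative_series,
    dn_ds,
    site_counts,
    sliding_windows,
)
from subpatterns.classify import CATEGORIES
from subpatterns.errors import SiteOutOfRangeError, WindowError


def _events_at(specs):
    """Minimal hand-built events: (site, category, from, to)."""
    from subpatterns.classify import SubstitutionEvent, codon_index, \
        codon_position

    events = []
    for site, category, from_base, to_base in specs:
        mclass = "Ts" if category in ("As", "Aa") else "Tv"
        effect = "synonymous" if category in ("As", "Bs") else "nonsynonymous"
        events.append(SubstitutionEvent(
            branch=(9, 1), site=site, codon_index=codon_index(site),
            codon_position=codon_position(site), from_base=from_base,
            to_base=to_base, from_codon="NNN", to_codon="NNN",
            mutation_class=mclass, effect=effect, category=category,
        ))
    return events


def test_site_counts_tallies_by_category():
    events = _events_at([(10, "As", "A", "G"), (10, "As", "A", "G"),
                         (10, "Ba", "A", "C")])
    profile = site_counts(events, length=12)
    assert profile.counts["As"][9] == 2
    assert profile.counts["Ba"][9] == 1
    assert profile.ts[9] == 2 and profile.tv[9] == 1
    assert profile.total_events == 3
    assert profile.type_by_position.loc["A>G", 1] == 2
    assert profile.type_by_position.loc["A>C", 1] == 1


def test_site_counts_empty_and_out_of_range():
    profile = site_counts([], length=9)
    assert profile.total_events == 0
    with pytest.raises(SiteOutOfRangeError):
        site_counts(_events_at([(10, "As", "A", "G")]), length=9)


def test_site_counts_match_ground_truth(oracle_log, oracle_doc):
    events = build_events(oracle_doc)
    profile = site_counts(events, oracle_doc.alignment_length)
    truth = oracle_log.category_totals()
    for cat in CATEGORIES:
        assert profile.counts[cat].sum() == truth[cat]
    assert profile.ts.sum() + profile.tv.sum() == len(oracle_log.events)
    assert int(profile.type_by_position.values.sum()) == len(oracle_log.events)


def test_window_means_first_window():
    events = _events_at([(1, "As", "A", "G"), (3, "As", "A", "G"),
                         (3, "As", "G", "A")])
    profile = site_counts(events, length=9)
    series = sliding_windows(profile, window=3, step=3)
    assert series.window_starts[0] == 1
    assert series.means["As"][0] == pytest.approx(1.0)
    assert series.means["Aa"][0] == 0.0


def test_single_window_equals_genome_wide_mean(oracle_doc):
    events = build_events(oracle_doc)
    length = oracle_doc.alignment_length
    profile = site_counts(events, length)
    series = sliding_windows(profile, window=length, step=1)
    assert series.n_windows == 1
    for cat in CATEGORIES:
        assert series.means[cat][0] == pytest.approx(
            profile.counts[cat].sum() / length
        )


def test_tiling_windows_reproduce_genome_wide_mean(oracle_doc):
    """With step = window, coverage-weighted window means equal the global
    mean over the covered prefix (algebraic identity, checked numerically)."""
    events = build_events(oracle_doc)
    length = oracle_doc.alignment_length
    profile = site_counts(events, length)
    window = 45
    series = sliding_windows(profile, window=window, step=window)
    covered = series.n_windows * window
    for cat in CATEGORIES:
        tiled_mean = series.means[cat].mean()
        prefix_mean = profile.counts[cat][:covered].sum() / covered
        assert tiled_mean == pytest.approx(prefix_mean)


def test_window_bounds_are_enforced():
    profile = site_counts([], length=30)
    with pytest.raises(WindowError):
        sliding_windows(profile, window=2, step=1)
    with pytest.raises(WindowError):
        sliding_windows(profile, window=31, step=1)
    with pytest.raises(WindowError):
        sliding_windows(profile, window=9, step=0)


def test_windows_are_views_not_mutations(oracle_doc):
    events = build_events(oracle_doc)
    profile = site_counts(events, oracle_doc.alignment_length)
    before = {c: profile.counts[c].copy() for c in CATEGORIES}
    sliding_windows(profile, window=30, step=3)
    sliding_windows(profile, window=90, step=9)
    cumulative_series(profile, step=5)
    for cat in CATEGORIES:
        assert np.array_equal(profile.counts[cat], before[cat])


def test_dn_ds_values_and_undefined_marker():
    # dN = 0, dS > 0 -> 0; dN = dS -> 1; dS = 0 -> NaN
    events = _events_at([
        (1, "As", "A", "G"),                       # window 1: dS only
        (4, "As", "A", "G"), (5, "Aa", "C", "T"),  # window 2: dN = dS
        (8, "Ba", "A", "C"),                       # window 3: dN only
    ])
    profile = site_counts(events, length=9)
    series = sliding_windows(profile, window=3, step=3)
    ratio = dn_ds(series)
    assert ratio[0] == 0.0
    assert ratio[1] == pytest.approx(1.0)
    assert np.isnan(ratio[2])
    assert not np.isinf(ratio).any()


def test_cumulative_series_prefix_sums(oracle_log, oracle_doc):
    events = build_events(oracle_doc)
    profile = site_counts(events, oracle_doc.alignment_length)
    series = cumulative_series(profile, step=7)
    # nondecreasing, conserved, and equal to direct prefix sums over the log
    truth = oracle_log.category_totals()
    for cat in CATEGORIES:
        assert (np.diff(series.totals[cat]) >= 0).all()
        assert series.totals[cat][-1] == truth[cat]
        for pos, val in zip(series.positions, series.totals[cat]):
            direct = sum(1 for ev in oracle_log.events
                         if ev.category == cat and ev.site <= pos)
            assert val == direct
    assert series.kt[-1] == len(oracle_log.events)
    assert np.array_equal(
        series.kt, sum(series.totals[c] for c in CATEGORIES)
    )


def test_cumulative_series_zero_profile():
    profile = site_counts([], length=20)
    series = cumulative_series(profile, step=6)
    assert series.positions[-1] == 20
    assert series.kt.sum() == 0
    with pytest.raises(WindowError):
        cumulative_series(profile, step=0)
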