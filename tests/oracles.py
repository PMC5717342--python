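"""Independent brute-force oracles shared across test modules."""

from __future__ import annotations


def day_coverage_episodes(purchases, stretch=1.1, gap_days=15):
    """Episode construction by marking individual supplied days on a day grid.

    For each purchase (in date order) the supply starts at the purchase day
    or, if supply is still running, when it ends (carry-over); every supplied
    day is marked.  Runs of marked days separated by at most ``gap_days``
    are bridged into one episode.  Returns (start, end, duration) per
    episode; requires integral supply spans (ddd * stretch an integer).
    """
    supplied = set()
    next_free = 0
    for day, ddd in sorted(purchases):
        span = int(round(ddd * stretch))
        start = max(day, next_free)
        supplied.update(range(start, start + span))
        next_free = start + span
    if not supplied:
        return []
    days = sorted(supplied)
    runs = [[days[0], days[0] + 1]]
    for d in days[1:]:
        if d - runs[-1][1] <= gap_days:
            runs[-1][1] = d + 1
        else:
            runs.append([d, d + 1])
    return [(s, e, e - s) for s, e in runs]
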