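"""Independent brute-force validator of the rule-based filter criteria.

Recomputes every click-train and vessel criterion from a raw pulse list
using plain Python and the :mod:`statistics` module -- deliberately
sharing no code path (and no numpy) with the package implementation, so
the two can cross-check each other flag-for-flag.
"""

import statistics


def brute_remove_reflections(pulses, min_pi_ms=2.0):
    """pulses: list of (t_ms, spl_a, spl_b, td_us) tuples, time-sorted."""
    kept = []
    for p in pulses:
        if not kept or p[0] - kept[-1][0] >= min_pi_ms:
            kept.append(p)
    return kept


def brute_segments(pulses, threshold_ms, inclusive_stay):
    """Split at gaps; ``inclusive_stay`` True means a gap == threshold stays."""
    segments = []
    current = []
    for p in pulses:
        if current:
            gap = p[0] - current[-1][0]
            split = gap > threshold_ms if inclusive_stay else gap >= threshold_ms
            if split:
                segments.append(current)
                current = []
        current.append(p)
    if current:
        segments.append(current)
    return segments


def brute_click_flags(segment):
    """The nine click-train criterion flags for one segment."""
    n = len(segment)
    times = [p[0] for p in segment]
    intervals = [b - a for a, b in zip(times, times[1:])]
    flags = {"min_pulse_interval": True, "max_pulse_interval": True}
    flags["min_pulses"] = n >= 6
    if len(intervals) >= 2:
        sd = statistics.stdev(intervals)
        flags["cv_pulse_interval"] = sd / statistics.mean(intervals) <= 0.4
    else:
        flags["cv_pulse_interval"] = False
    flags["median_pulse_interval"] = (
        bool(intervals) and statistics.median(intervals) < 100.0
    )
    ratios = [p[1] / p[2] for p in segment]
    flags["splr"] = statistics.mean(ratios) >= 0.6 if ratios else False
    flags["duration"] = n >= 2 and times[-1] - times[0] >= 12.0
    tds = [p[3] for p in segment]
    flags["sd_td"] = n >= 2 and statistics.stdev(tds) < 25.0
    spls = [p[1] for p in segment]
    if n >= 2:
        cv_pct = statistics.stdev(spls) / statistics.mean(spls) * 100.0
        flags["cv_spl_a"] = cv_pct <= 100.0
    else:
        flags["cv_spl_a"] = False
    return flags


def brute_vessel_flags(segment):
    """The three vessel criterion flags for one segment."""
    times = [p[0] for p in segment]
    return {
        "max_pulse_interval": True,
        "min_pulses": len(segment) > 80,
        "duration": times[-1] - times[0] >= 10_000.0,
    }


def brute_click_candidates(pulses):
    """Full click branch: clean, split at > 100 ms, flag segments >= 2 pulses."""
    cleaned = brute_remove_reflections(pulses, 2.0)
    out = []
    for seg in brute_segments(cleaned, 100.0, inclusive_stay=True):
        if len(seg) >= 2:
            out.append((seg[0][0], seg[-1][0], brute_click_flags(seg)))
    return out


def brute_vessel_candidates(pulses):
    """Full vessel branch on the raw list: split at >= 500 ms."""
    out = []
    for seg in brute_segments(pulses, 500.0, inclusive_stay=False):
        if len(seg) >= 2:
            out.append((seg[0][0], seg[-1][0], brute_vessel_flags(seg)))
    return out
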