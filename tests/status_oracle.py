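"""Brute-force reference for the visit-status rule.

A literal, line-by-line restatement of the classification sentences, written
against plain Python dates and lists so it shares no code with the
implementation under test.
"""

import datetime

ORDER = ["NMC", "SMC", "MCI", "D"]


def oracle_status(events, visit_date, window_days=365, policy="printed_pairs"):
    """events: list of (datetime.date, category) pairs; returns final category.

    Baseline: a participant is SMC/MCI/D if at least one event of that
    category is dated on or before the visit; the most severe such category
    wins; with no prior events the participant is NMC. Upgrade: SMC followed
    by MCI within the window after the visit is MCI; MCI followed by dementia
    within the window is dementia (strictly after the visit, at most
    window_days later).
    """
    before = [cat for d, cat in events if d <= visit_date]
    baseline = "NMC"
    for cat in before:
        if ORDER.index(cat) > ORDER.index(baseline):
            baseline = cat

    lo = visit_date
    hi = visit_date + datetime.timedelta(days=window_days)
    after = [cat for d, cat in events if lo < d <= hi]

    if policy == "none":
        return baseline
    if policy == "printed_pairs":
        if baseline == "SMC" and "MCI" in after:
            return "MCI"
        if baseline == "MCI" and "D" in after:
            return "D"
        return baseline
    if policy == "max_within_window":
        if baseline == "NMC":
            return baseline
        final = baseline
        for cat in after:
            if ORDER.index(cat) > ORDER.index(final):
                final = cat
        return final
    raise ValueError(policy)
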