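"""Independent brute-force reference implementations of the learning measures.

Deliberately naive, direct translations of the verbal definitions, kept free
of any code shared with the package so they can serve as oracles:
every window is scanned explicitly, every deviation evaluated pointwise.
"""

from __future__ import annotations


def ttc_oracle(correct, session_ids=None, window=20, accuracy=0.80):
    """Exhaustive scan over all in-session windows of `window` response
    trials; returns the 1-based index of the last trial of the first
    qualifying window, else None."""
    n = len(correct)
    if session_ids is None:
        session_ids = [1] * n
    for end in range(window, n + 1):
        win = list(range(end - window, end))
        if len({session_ids[i] for i in win}) != 1:
            continue
        if sum(correct[i] for i in win) / window >= accuracy - 1e-12:
            return end
    return None


def change_point_oracle(correct):
    """Pointwise evaluation of d(t) = chord(t) - cumulative(t) in exact
    rational arithmetic; ties resolved to the earliest trial.  Returns
    (cp_index_1based, deviations, degenerate)."""
    from fractions import Fraction

    n = len(correct)
    cum = []
    total = 0
    for c in correct:
        total += c
        cum.append(total)
    first, last = cum[0], cum[-1]
    devs = []
    for t in range(1, n + 1):
        line = Fraction(first) + Fraction(last - first) * (t - 1) / (n - 1)
        devs.append(line - cum[t - 1])
    best = max(devs)
    if best <= 0:
        return 1, [float(d) for d in devs], True
    return devs.index(best) + 1, [float(d) for d in devs], False


def maxci_oracle(correct):
    best = 0
    run = 0
    for c in correct:
        if c:
            run = 0
        else:
            run += 1
            if run > best:
                best = run
    return best


def regress_oracle(correct, block=5):
    """One-trial-step moving window: every position with a full prior and
    next block; accumulate positive declines in proportion correct; divide
    by the number of trials."""
    n = len(correct)
    if n < 2 * block:
        return None
    total = 0.0
    for i in range(block, n - block + 1):
        prior = sum(correct[i - block : i]) / block
        nxt = sum(correct[i : i + block]) / block
        if nxt < prior:
            total += prior - nxt
    return total / n


def fs_oracle(correct):
    """Direct counting of post-loss and post-win accuracies."""
    lose = [correct[i] for i in range(1, len(correct)) if not correct[i - 1]]
    win = [correct[i] for i in range(1, len(correct)) if correct[i - 1]]
    p_ls = sum(lose) / len(lose) if lose else None
    p_ws = sum(win) / len(win) if win else None
    fs = p_ls - p_ws if (p_ls is not None and p_ws is not None) else None
    return fs, p_ls, p_ws
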