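"""Shared test utilities."""

import numpy as np


def match_events(detected, annotated, tol_s: float = 0.03) -> int:
    """Greedy one-to-one matching of event times within a tolerance."""
    det = np.asarray(detected, dtype=float)
    used = np.zeros(len(det), dtype=bool)
    hits = 0
    for t in np.asarray(annotated, dtype=float):
        d = np.abs(det - t)
        d[used] = np.inf
        if len(d) and np.min(d) <= tol_s:
            used[np.argmin(d)] = True
            hits += 1
    return hits
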