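"""Independent brute-force oracles and tiny fixtures shared by test modules."""

import numpy as np
import pandas as pd


def make_tiny_peptides():
    """Two dogs, two proteins, exact 4-fold shift; for closed-form checks."""
    rows = []
    for dog, d0, d7 in [("dogA", 10.0, 40.0), ("dogB", 8.0, 32.0)]:
        for acc, mult in [("P1", 1.0), ("P2", 2.0)]:
            for pep in ("p1", "p2"):
                rows.append((dog, "D0", f"{dog}_D0", acc, f"{acc}_{pep}", d0 * mult))
                rows.append((dog, "D7", f"{dog}_D7", acc, f"{acc}_{pep}", d7 * mult))
    return pd.DataFrame(
        rows,
        columns=[
            "dog_id",
            "timepoint",
            "sample_id",
            "protein_accession",
            "peptide_id",
            "abundance",
        ],
    )


def brute_force_es(scores, hit_positions, weight=1.0):
    """Position-by-position running sum; returns the value of largest |.|."""
    n = len(scores)
    hits = set(int(h) for h in hit_positions)
    nr = sum(abs(scores[p]) ** weight for p in hits)
    vals = []
    run = 0.0
    for j in range(n):
        if j in hits:
            run += (abs(scores[j]) ** weight / nr) if nr > 0 else 1.0 / len(hits)
        else:
            run -= 1.0 / (n - len(hits))
        vals.append(run)
    return vals[int(np.argmax(np.abs(vals)))]
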