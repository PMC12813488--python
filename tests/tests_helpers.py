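"""Small helpers shared across test modules."""

import numpy as np

from connsig import subject_connectome


def cohort_edges(cohort):
    """Edge matrix + aligned table for a cross-sectional cohort."""
    rows, ids = [], []
    for sid in cohort.table["subject_id"]:
        ev = subject_connectome(cohort.runs[sid], labels=cohort.labels)
        if ev is None:
            continue
        rows.append(ev.values)
        ids.append(sid)
    table = cohort.table.set_index("subject_id").loc[ids].reset_index()
    return np.vstack(rows), table


def paired_edges(dep_cohort):
    """Paired (typical, deprived) edge matrices plus the aligned table.

    Complete pairs only: subjects with an ineligible session are excluded.
    """
    Xt, Xd, keep = [], [], []
    for i, sid in enumerate(dep_cohort.table["subject_id"]):
        a = subject_connectome(dep_cohort.runs_typical[sid])
        b = subject_connectome(dep_cohort.runs_deprived[sid])
        if a is None or b is None:
            continue
        Xt.append(a.values)
        Xd.append(b.values)
        keep.append(i)
    table = dep_cohort.table.iloc[keep].reset_index(drop=True)
    return np.vstack(Xt), np.vstack(Xd), table
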