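"""Reference tallies for the archaeological worked example.

Per-site, per-tooth counts of archaeological reindeer lower molars assigned by
linear discriminant analysis to mountain (*R. t. tarandus*) or forest
(*R. t. fennicus*) reindeer at four Sámi sites in northern Fennoscandia
(13th-19th century).  These tallies serve as the worked example for
:func:`molargm.summarize_assignments`.
"""

from __future__ import annotations

import pandas as pd

#: (site, tooth) -> (n assigned to mountain reindeer, n assigned to forest reindeer)
ARCHAEOLOGICAL_ASSIGNMENT_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("Juikenttä", "m1"): (0, 1),
    ("Juikenttä", "m2"): (0, 1),
    ("Markkina", "m1"): (19, 2),
    ("Markkina", "m2"): (21, 2),
    ("Nukkumajoki", "m1"): (7, 3),
    ("Nukkumajoki", "m2"): (13, 5),
    ("Pappila", "m1"): (4, 0),
    ("Pappila", "m2"): (12, 0),
}


def archaeological_assignments() -> pd.DataFrame:
    """Expand the per-site tallies into one assignment row per tooth."""
    rows = []
    for (site, tooth), (n_mountain, n_forest) in ARCHAEOLOGICAL_ASSIGNMENT_COUNTS.items():
        rows.extend(
            dict(site=site, tooth=tooth, assigned="mountain") for _ in range(n_mountain)
        )
        rows.extend(
            dict(site=site, tooth=tooth, assigned="forest") for _ in range(n_forest)
        )
    return pd.DataFrame(rows)
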