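"""Bundled reference tables.

``soybean14_panel()`` loads the published pairwise polymorphism table of a
14-cultivar soybean panel scored with 165 INDEL markers — polymorphic-marker
counts above the diagonal, integer percentages of the 165-marker total below
it.  It serves as a real-data check of the pairwise-scoring arithmetic and
as a ready-made distance source for clustering examples.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from indelmark.io import read_pairwise_table

#: marker total behind the bundled panel table
SOYBEAN14_TOTAL_MARKERS = 165


def soybean14_panel() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts and percentage matrices of the bundled 14-cultivar soybean panel."""
    ref = resources.files("indelmark.data") / "soybean14_panel_pairwise.tsv"
    with resources.as_file(ref) as path:
        return read_pairwise_table(path)
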