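"""AAL-116 node table: region labels for whole-brain (cerebrum + cerebellum) networks.

The parcellation has 116 regions — 90 cerebral and 26 cerebellar/vermis — indexed
1..116 in the conventional atlas order (odd = left, even = right for paired
regions; vermis regions 109-116 are midline). Only the label table is shipped;
spatial definitions are out of scope.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_node_table", "region_labels"]


def load_node_table() -> pd.DataFrame:
    """Return the 116-row node table.

    Columns: ``index`` (1-based atlas index), ``name``, ``abbreviation``
    (e.g. ``PreCG.R``, ``LING.L``, ``CRBLCrus1.R``, ``Vermis3``),
    ``hemisphere`` (``L``/``R``/``M``) and ``division``
    (``cerebrum``/``cerebellum``).
    """
    with resources.files("topofc.data").joinpath("aal116.csv").open() as fh:
        table = pd.read_csv(fh)
    return table


def region_labels() -> list[str]:
    """Abbreviated labels for the 116 regions, in atlas order."""
    return load_node_table()["abbreviation"].tolist()
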