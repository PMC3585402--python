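"""Small bundled reference tables."""

from importlib import resources

import pandas as pd

from .phase import read_homolog_phase_table


def mouse_zebrafish_phase_table() -> pd.DataFrame:
    """Published circadian peak phases of homologous mouse/zebrafish genes.

    Mouse phases are averages across tissues of a multi-tissue circadian
    expression compendium; zebrafish phases are whole-larva joint LD/DD calls.
    Zebrafish entries without a detected homolog or without rhythmicity carry
    the literal markers "Not present" / "Not oscillating".
    """
    ref = resources.files("circanet") / "data" / "mouse_zebrafish_circadian_phases.tsv"
    with resources.as_file(ref) as path:
        return read_homolog_phase_table(path)
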