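"""Access to the shipped flavonoid knowledge directory.

The residue/domain/specificity tables encode published knowledge
(chalcone-synthase diagnostics Q166/Q167, the malonyl-CoA-binding motif
313-329, the DFR substrate-specificity site); the bait FASTA files are
synthetic stand-in families with those diagnostics planted, generated at
a fixed seed by ``scripts/make_shipped_data.py``.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .knowledge_base import Reaction, load_pathway


def flavonoid_knowledge_dir() -> Path:
    """Directory holding the shipped flavonoid bait files and tables."""
    return Path(str(resources.files("pathscreen"))) / "data" / "flavonoid"


def load_flavonoid_pathway() -> list[Reaction]:
    """The shipped flavonoid reactions (synthetic baits, real rules)."""
    return load_pathway(flavonoid_knowledge_dir() / "config.tsv")
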