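"""Access to the small packaged fixtures.

All fixtures are illustrative open data shipped for demos and tests: a
12-node toy interactome with two 4-gene seed sets, a hand-curated core
coagulation gene list, a small MS GWAS gene list, and a miniature GWAS
Catalog associations table.
"""

from importlib.resources import files
from pathlib import Path

_DATA = files("crossnet") / "data"


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (e.g. ``toy_interactome.tsv``)."""
    path = Path(str(_DATA / name))
    if not path.exists():
        raise FileNotFoundError(f"no packaged fixture named {name!r}")
    return path


def toy_interactome() -> Path:
    return fixture_path("toy_interactome.tsv")


def toy_set_a() -> Path:
    return fixture_path("toy_set_a.txt")


def toy_set_b() -> Path:
    return fixture_path("toy_set_b.txt")


def coagulation_genes() -> Path:
    return fixture_path("coagulation_genes.txt")


def ms_gwas_genes() -> Path:
    return fixture_path("ms_gwas_genes.txt")


def toy_gwas_catalog() -> Path:
    return fixture_path("toy_gwas_catalog.tsv")
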