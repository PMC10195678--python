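"""Locating and fetching the mouse mitochondrial reference genome.

The design workflow is reference-agnostic, but the canonical use case
targets the mouse mtDNA reference NC_005089 (GRCm38 ChrM, 16,299 bp,
13 protein-coding genes Nd1..Cytb).  Reference sequence data is not
redistributed with this package; place a GenBank flat file of
NC_005089 (with CDS features) at the path returned by
:func:`default_reference_path`, or call :func:`fetch_reference` once
on a machine with network access.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

from .genome import GeneFeature, MitoGenome, load_genome

REFERENCE_ACCESSION = "NC_005089"

#: The 13 protein-coding genes of mouse mtDNA, in genome order.
MOUSE_PROTEIN_GENES = [
    "ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3",
    "ND3", "ND4L", "ND4", "ND5", "ND6", "CYTB",
]

#: Common aliases -> RefSeq gene symbols.
GENE_ALIASES = {
    "Nd1": "ND1", "Nd2": "ND2", "Nd3": "ND3", "Nd4": "ND4", "Nd4l": "ND4L",
    "Nd5": "ND5", "Nd6": "ND6", "Cytb": "CYTB", "CoI": "COX1", "CoII": "COX2",
    "CoIII": "COX3", "Atp6": "ATP6", "Atp8": "ATP8",
}


def default_reference_path() -> Path:
    return Path(__file__).parent / "data" / f"{REFERENCE_ACCESSION}.gb"


def load_mouse_reference(
    path: Optional[str | Path] = None,
) -> tuple[MitoGenome, list[GeneFeature]]:
    """Load NC_005089 from ``path`` or the packaged data directory.

    Raises ``FileNotFoundError`` with fetch instructions when the file
    is absent (the sequence is not redistributed with the package).
    """
    path = Path(path) if path is not None else default_reference_path()
    if not path.exists():
        raise FileNotFoundError(
            f"mouse mtDNA reference not found at {path}; fetch it once with\n"
            f"  mitostop fetch-reference --email you@example.org\n"
            f"or download {REFERENCE_ACCESSION} in GenBank (full) format from "
            f"NCBI and save it there"
        )
    genome, features = load_genome(path, circular=True)
    for f in features:
        f.gene_name = GENE_ALIASES.get(f.gene_name, f.gene_name).upper()
    return genome, features


def fetch_reference(
    dest: Optional[str | Path] = None, email: str = ""
) -> Path:
    """Download NC_005089 (GenBank flat file) via NCBI E-utilities."""
    from Bio import Entrez

    dest = Path(dest) if dest is not None else default_reference_path()
    dest.parent.mkdir(parents=True, exist_ok=True)
    Entrez.email = email or "anonymous@example.org"
    with Entrez.efetch(
        db="nuccore", id=REFERENCE_ACCESSION, rettype="gb", retmode="text"
    ) as handle:
        dest.write_text(handle.read())
    return dest
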