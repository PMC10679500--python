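"""Retrieval of the published reference inputs (UniProt FASTA, PDB entries).

The real-data checks of the pipeline need the study sequences (UniProt
P11678 eosinophil peroxidase, P05164 myeloperoxidase) and crystal structures
(PDB 8OGI eosinophil peroxidase, 1CXP and related myeloperoxidase entries).
These are small public downloads; this module fetches them into a local
cache and reuses cached copies, so an offline run succeeds if the files were
placed there beforehand (set ``PEROXIKIT_DATA_DIR`` or use the default
``~/.cache/peroxikit``).
"""

from __future__ import annotations

import os
import urllib.request
from pathlib import Path

__all__ = ["DataUnavailableError", "cache_dir", "fetch_uniprot_fasta", "fetch_pdb"]

UNIPROT_URL = "https://rest.uniprot.org/uniprotkb/{acc}.fasta"
PDB_URL = "https://files.rcsb.org/download/{pdb_id}.pdb"


class DataUnavailableError(RuntimeError):
    """Raised when a reference file is neither cached nor downloadable."""


def cache_dir() -> Path:
    root = os.environ.get("PEROXIKIT_DATA_DIR")
    path = Path(root) if root else Path.home() / ".cache" / "peroxikit"
    path.mkdir(parents=True, exist_ok=True)
    return path


def _fetch(url: str, target: Path, timeout: float) -> Path:
    if target.exists() and target.stat().st_size > 0:
        return target
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except Exception as exc:
        raise DataUnavailableError(
            f"cannot download {url} and no cached copy at {target}; place the "
            f"file there manually for offline use ({exc})") from exc
    target.write_bytes(data)
    return target


def fetch_uniprot_fasta(accession: str, timeout: float = 10.0) -> Path:
    """Return a local path to the UniProt FASTA for ``accession``."""
    return _fetch(UNIPROT_URL.format(acc=accession),
                  cache_dir() / f"{accession}.fasta", timeout)


def fetch_pdb(pdb_id: str, timeout: float = 20.0) -> Path:
    """Return a local path to the PDB-format coordinates for ``pdb_id``."""
    pdb_id = pdb_id.upper()
    return _fetch(PDB_URL.format(pdb_id=pdb_id),
                  cache_dir() / f"{pdb_id}.pdb", timeout)
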