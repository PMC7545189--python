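"""Opt-in retrieval of deposited structures from the Protein Data Bank.

Network access is never implicit: library calls operate on local files only,
and this helper is invoked solely by the explicitly flagged CLI command (or
directly by a user script).  Downloads are cached as plain PDB/mmCIF text so
repeated analyses are offline after the first fetch.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

__all__ = ["DEFAULT_CACHE", "FetchError", "fetch_structure", "cached_path"]

DEFAULT_CACHE = Path("data/structures")
_URL = "https://files.rcsb.org/download/{code}.{ext}"


class FetchError(RuntimeError):
    """Raised when a structure cannot be downloaded."""


def cached_path(accession: str, cache_dir: str | Path = DEFAULT_CACHE, fmt: str = "pdb") -> Path:
    ext = "cif" if fmt in ("cif", "mmcif") else "pdb"
    return Path(cache_dir) / f"{accession.upper()}.{ext}"


def fetch_structure(
    accession: str,
    cache_dir: str | Path = DEFAULT_CACHE,
    fmt: str = "pdb",
    timeout: float = 60.0,
) -> Path:
    """Download one accession into the cache (no-op if already present)."""
    accession = accession.upper()
    if len(accession) != 4 or not accession.isalnum():
        raise ValueError(f"not a PDB accession: {accession!r}")
    dest = cached_path(accession, cache_dir, fmt)
    if dest.exists():
        return dest
    dest.parent.mkdir(parents=True, exist_ok=True)
    url = _URL.format(code=accession, ext=dest.suffix.lstrip("."))
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            text = resp.read().decode("utf-8", errors="replace")
    except (urllib.error.URLError, OSError) as exc:
        raise FetchError(f"could not download {accession} from {url}: {exc}") from exc
    dest.write_text(text)
    return dest
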