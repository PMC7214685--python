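"""Optional retrieval of public structure entries.

Everything else in the package is offline; resolving a 4-character
accession to coordinates over the network happens only when the caller
explicitly opts in (``--fetch`` on the CLI).
"""

from __future__ import annotations

import os
import urllib.request

RCSB_URL = "https://files.rcsb.org/download/{code}.{ext}"


def resolve_input(source: str, fetch: bool = False, cache_dir: str = ".") -> str:
    """Return a local path for ``source``.

    Existing paths pass through.  A bare 4-character accession is looked up
    as ``<cache_dir>/<CODE>.{pdb,cif}``; with ``fetch=True`` a missing entry
    is downloaded from the public archive (mmCIF) into the cache first.
    """
    if os.path.exists(source):
        return source
    code = source.strip().upper()
    if len(code) != 4 or not code[0].isdigit():
        raise FileNotFoundError(f"{source!r} is neither a file nor an accession")
    for ext in ("pdb", "cif"):
        cached = os.path.join(cache_dir, f"{code}.{ext}")
        if os.path.exists(cached):
            return cached
    if not fetch:
        raise FileNotFoundError(
            f"no local copy of {code} in {cache_dir!r}; pass --fetch to download"
        )
    os.makedirs(cache_dir, exist_ok=True)
    dest = os.path.join(cache_dir, f"{code}.cif")
    urllib.request.urlretrieve(RCSB_URL.format(code=code, ext="cif"), dest)
    return dest
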