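#!/usr/bin/env python
"""One-time fetch of the catalogued NCBI accessions (network required).

Downloads the insect and human cytochrome b561 protein sequences referenced
by the bundled identity table plus the six human references, and writes them
to data/ncbi/cytb561_sequences.fasta. The library and the test suite never
perform network access themselves; the accession-based acceptance checks
read the file this script produces.

Usage:
    python scripts/fetch_ncbi.py [--email you@example.org]
"""

from __future__ import annotations

import argparse
import time
import urllib.parse
import urllib.request
from pathlib import Path

from cytb561.seqio import load_table1_fixture

HUMAN_REFERENCES = {
    "NP_079119.3": "Dcytb",
    "NP_705839.3": "Lcytb",
    "NP_001017916.1": "CGcytb",
    "NP_001278213.1": "TScytb",
    "NP_872386.1": "CYB561D1",
    "NP_001347970.1": "SDR2",
}

EUTILS = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
OUT = Path(__file__).resolve().parent.parent / "data" / "ncbi" / "cytb561_sequences.fasta"


def fetch_batch(accessions: list[str], email: str) -> str:
    params = urllib.parse.urlencode(
        {
            "db": "protein",
            "id": ",".join(accessions),
            "rettype": "fasta",
            "retmode": "text",
            "email": email,
            "tool": "cytb561-fetch",
        }
    )
    with urllib.request.urlopen(f"{EUTILS}?{params}", timeout=60) as resp:
        return resp.read().decode()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--email", default="anonymous@example.org")
    args = parser.parse_args()

    accessions = list(load_table1_fixture().accessions) + list(HUMAN_REFERENCES)
    OUT.parent.mkdir(parents=True, exist_ok=True)
    chunks = [accessions[i : i + 20] for i in range(0, len(accessions), 20)]
    with open(OUT, "w") as fh:
        for chunk in chunks:
            text = fetch_batch(chunk, args.email)
            # NCBI returns the versioned accession as the FASTA id
            fh.write(text.rstrip() + "\n")
            time.sleep(0.5)
    print(f"wrote {len(accessions)} accessions to {OUT}")


if __name__ == "__main__":
    main()
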