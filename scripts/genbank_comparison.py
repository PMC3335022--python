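#!/usr/bin/env python
"""All-pairs ANI and tetranucleotide comparison of deposited SAG assemblies.

Optional integration run (off by default; requires data you download
yourself).  Fetch the five Verrucomicrobia SAG assemblies from Genbank
(accessions CAGK00000000, CAGL00000000, CAGM00000000, CAGN00000000,
GACO00000000), place them as FASTA files in one directory, then:

    python scripts/genbank_comparison.py <assembly_dir> [--out table.csv]

Closely related single-cell assemblies of one phylotype are expected to show
pairwise ANI above ~97.8 % and tetranucleotide signature correlations above
~0.96.
"""

from __future__ import annotations

import argparse
from pathlib import Path


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("assembly_dir", type=Path)
    parser.add_argument("--out", type=Path, default=None)
    args = parser.parse_args()

    from sagkit.workbench import compare_assembly_dir

    table = compare_assembly_dir(args.assembly_dir)
    print(table.to_string(index=False))
    if args.out is not None:
        table.to_csv(args.out, index=False, float_format="%.10g")


if __name__ == "__main__":
    main()
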