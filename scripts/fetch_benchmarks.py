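#!/usr/bin/env python
"""Download the classic community-detection benchmark networks and convert
them to plain edge lists ready for `reneel run`.

These are the unweighted, undirected, loop-free networks of the 10th DIMACS
implementation challenge clustering testbed (Adjnoun, Jazz, Metabolic,
Email, Polblog, Netscience, Power, PGPgc, Astro-ph, Memplus, As-22july06,
Cond-mat-2005, Smallworld, CAIDARouterLevel).  The SuiteSparse matrix
collection mirrors all of them in MatrixMarket form under the DIMACS10
group, which is the single provenance used here; the historical per-network
sources (the Arenas and Newman dataset pages, the original circuit and
router data) are reachable from each SuiteSparse entry's metadata.

This script needs network access and is never invoked by the test suite;
the library itself builds and tests entirely from synthetic fixtures.

Usage:
    python scripts/fetch_benchmarks.py --dest benchmarks [email jazz ...]
    reneel run benchmarks/email.edges --kmax 100 --kprime 20 --seed 1 -o out/email
"""

from __future__ import annotations

import argparse
import io
import tarfile
import urllib.request
from pathlib import Path

from scipy.io import mmread

BASE = "https://suitesparse-collection-website.herokuapp.com/MM/DIMACS10"

#: benchmark name -> SuiteSparse DIMACS10 matrix name
NETWORKS = {
    "adjnoun": "adjnoun",
    "jazz": "jazz",
    "metabolic": "celegans_metabolic",
    "email": "email",
    "polblog": "polblogs",
    "netscience": "netscience",
    "power": "power",
    "pgpgc": "PGPgiantcompo",
    "astro-ph": "astro-ph",
    "memplus": "memplus",
    "as-22july06": "as-22july06",
    "cond-mat-2005": "cond-mat-2005",
    "smallworld": "smallworld",
    "caidarouterlevel": "caidaRouterLevel",
}


def fetch(name: str, dest: Path) -> Path:
    matrix = NETWORKS[name]
    url = f"{BASE}/{matrix}.tar.gz"
    print(f"downloading {url}")
    with urllib.request.urlopen(url) as resp:
        blob = resp.read()
    with tarfile.open(fileobj=io.BytesIO(blob), mode="r:gz") as tar:
        member = next(m for m in tar.getmembers() if m.name.endswith(".mtx"))
        mtx = tar.extractfile(member)
        assert mtx is not None
        A = mmread(mtx).tocoo()
    out = dest / f"{name}.edges"
    n_written = 0
    with out.open("w") as fh:
        for u, v in zip(A.row, A.col):
            if u < v:  # store each undirected link once, drop any loops
                fh.write(f"{u} {v}\n")
                n_written += 1
    nodes = int(max(A.row.max(), A.col.max())) + 1
    print(f"  {name}: n={nodes} m={n_written} -> {out}")
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("names", nargs="*", default=[],
                    help=f"networks to fetch (default all): {', '.join(NETWORKS)}")
    ap.add_argument("--dest", type=Path, default=Path("benchmarks"))
    args = ap.parse_args()
    names = args.names or list(NETWORKS)
    unknown = set(names) - set(NETWORKS)
    if unknown:
        ap.error(f"unknown networks: {sorted(unknown)}")
    args.dest.mkdir(parents=True, exist_ok=True)
    for name in names:
        fetch(name, args.dest)


if __name__ == "__main__":
    main()
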