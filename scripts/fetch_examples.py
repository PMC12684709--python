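#!/usr/bin/env python
"""Download the two worked-example wwPDB entries (1x1u, 1u0b; ~100 kB each)
into tests/data/ so the worked-example acceptance tests can run.

Usage: python scripts/fetch_examples.py
"""
import os
import sys
import urllib.request

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
DATA = os.path.join(ROOT, "tests", "data")
URL = "https://files.rcsb.org/download/{}.pdb"


def main():
    os.makedirs(DATA, exist_ok=True)
    ok = True
    for pdb_id in ("1X1U", "1U0B"):
        path = os.path.join(DATA, f"{pdb_id.lower()}.pdb")
        if os.path.exists(path):
            print(f"{path}: already present")
            continue
        try:
            with urllib.request.urlopen(URL.format(pdb_id), timeout=60) as r:
                data = r.read()
            with open(path, "wb") as fh:
                fh.write(data)
            print(f"{path}: {len(data)} bytes")
        except Exception as exc:
            print(f"{pdb_id}: download failed: {exc}", file=sys.stderr)
            ok = False
    return 0 if ok else 1


if __name__ == "__main__":
    sys.exit(main())
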