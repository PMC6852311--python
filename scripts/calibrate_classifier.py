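"""Refit classifier intervals against curated labelled PDB structures.

Requires network access to fetch entries from the RCSB (or a local mirror
directory of pre-downloaded files).  The shipped default configuration was
chosen from kinase-domain structural conventions; running this script
against the known labelled exemplars prints the measured feature values so
the YAML intervals can be refitted, keeping thresholds as configuration
rather than code.

Usage:
    python scripts/calibrate_classifier.py --cache-dir pdb_cache/ [--fetch]

Labelled exemplars (class -> PDB chain):
    N-lobe:  collapsed/in 4QQ5:A, collapsed/inter 2G2H:B,
             collapsed/out 5HX6:A, stretched/in 3VHK:A,
             stretched/inter 4PMM:A, stretched/out 2W5B:A
    A-loop:  closed_type2 3V5Q:A, open_dfg_out 2HZI:A,
             closed_a_under_p 3BEA:A
    Extra:   ABL1 2HYY/3CS9/3OXZ (closed type 2, collapsed, αC-in),
             KDR 3WZE/4AG8 (closed A-under-P, stretched, αC-in)
"""

import argparse
import sys
import urllib.request
from pathlib import Path

from kinoforge.classifiers import FEATURE_NAMES, compute_features, default_config
from kinoforge.reference_numbering import number_chain
from kinoforge.structure_model import read_structure, select_chain

EXEMPLARS = {
    "4QQ5:A": "nlobe collapsed/in", "2G2H:B": "nlobe collapsed/inter",
    "5HX6:A": "nlobe collapsed/out", "3VHK:A": "nlobe stretched/in",
    "4PMM:A": "nlobe stretched/inter", "2W5B:A": "nlobe stretched/out",
    "3V5Q:A": "aloop closed_type2", "2HZI:A": "aloop open_dfg_out",
    "3BEA:A": "aloop closed_a_under_p",
    "2HYY:A": "ABL1 closed_type2/collapsed/in",
    "3CS9:A": "ABL1 closed_type2/collapsed/in",
    "3OXZ:A": "ABL1 closed_type2/collapsed/in",
    "3WZE:A": "KDR closed_a_under_p/stretched/in",
    "4AG8:A": "KDR closed_a_under_p/stretched/in",
}


def fetch(pdb_id: str, cache: Path) -> Path:
    path = cache / f"{pdb_id.lower()}.pdb"
    if not path.exists():
        url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
        print(f"fetching {url}", file=sys.stderr)
        urllib.request.urlretrieve(url, path)
    return path


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cache-dir", type=Path, required=True)
    ap.add_argument("--fetch", action="store_true",
                    help="Download missing entries from the RCSB.")
    args = ap.parse_args()
    args.cache_dir.mkdir(parents=True, exist_ok=True)
    config = default_config()
    print("entry\tlabel\t" + "\t".join(FEATURE_NAMES))
    for spec, label in EXEMPLARS.items():
        pdb_id, _, chain_id = spec.partition(":")
        path = args.cache_dir / f"{pdb_id.lower()}.pdb"
        if not path.exists():
            if not args.fetch:
                print(f"{spec}\t{label}\tMISSING (use --fetch)", file=sys.stderr)
                continue
            path = fetch(pdb_id, args.cache_dir)
        structure = read_structure(path)
        chain = select_chain(structure, chain_id, 0)
        domain = number_chain(chain, name=pdb_id)
        fv = compute_features(domain, config)
        values = "\t".join("" if fv.get(n) is None else f"{fv.get(n):.2f}"
                           for n in FEATURE_NAMES)
        print(f"{spec}\t{label}\t{values}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
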