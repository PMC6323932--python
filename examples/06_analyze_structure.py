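"""Full pipeline on a structure file.

Writes a synthetic PDB (open trefoil with CA trace), parses it back, and
runs the complete per-chain analysis; the same report is produced by the
command line:  protknot analyze chain.pdb
"""

import json
import tempfile
from pathlib import Path

from protknot import AnalysisOptions, analyze_chain, parse_structure
from protknot.fixtures import FixtureSpec, make_fixture, write_fixture_pdb

with tempfile.TemporaryDirectory() as tmp:
    pdb = Path(tmp) / "open_trefoil.pdb"
    write_fixture_pdb(make_fixture(FixtureSpec("open_trefoil", n_vertices=60)), pdb)

    (chain,) = parse_structure(pdb)
    report = analyze_chain(
        chain,
        AnalysisOptions(n_closures=60, n_directions=60, fingerprint_n=10, stride=10),
    )

print(f"chain {report['chain']}: {report['n_residues']} residues")
print(f"knots:    dominant {report['knots']['dominant']} "
      f"(p={report['knots']['probability']:.2f}), "
      f"core {report['knots'].get('core')}")
print(f"knotoids: dominant {report['knotoids']['dominant']} "
      f"(p={report['knotoids']['probability']:.2f})")
print(f"labels:   {report['labels']}")
print("\nfull JSON report keys:", sorted(report))
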