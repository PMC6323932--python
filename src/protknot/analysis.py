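"""Full per-chain analysis pipeline.

Runs, for one chain: bridge detection, the probabilistic knot spectrum
and knotting fingerprint, the knotoid distribution / projection globe /
knotoid fingerprint, deterministic covalent-loop knots, and cystine-knot
motifs — and assembles a JSON-serializable report with every sampling
descriptor embedded for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import __version__
from .covalent_loops import bridged_open_paths, enumerate_covalent_loops, loop_knot_type
from .cysteine_knots import detect_cysteine_knots, verify_ck_loops_unknotted
from .errors import TopologyError
from .fingerprints import (
    classify_entanglement,
    knot_fingerprint,
    knotoid_fingerprint,
    locate_core,
)
from .probabilistic import dominant_type, projection_globe
from .structure_io import (
    ChainModel,
    declare_bridges,
    detect_disulfide_bridges,
    detect_ion_bridges,
    extract_backbone,
)

__all__ = ["AnalysisOptions", "analyze_chain"]

REPORT_SCHEMA_VERSION = 1


@dataclass
class AnalysisOptions:
    n_closures: int = 100
    n_directions: int = 100
    stride: int | None = None
    fingerprint_n: int = 20
    seed: int | None = None
    ss_cutoff: float = 2.5
    ion_cutoff: float = 3.0
    max_bridges: int = 2
    skip: set[str] = field(default_factory=set)  # subset of {knotoids, loops, ck, fingerprints}
    extra_bridges: list[tuple[int, int, str]] = field(default_factory=list)


def _spectrum_dict(spectrum) -> dict:
    return {t.name: round(p, 6) for t, p in sorted(
        spectrum.probabilities.items(), key=lambda kv: -kv[1]
    )}


def analyze_chain(chain: ChainModel, opts: AnalysisOptions | None = None) -> dict:
    """Analyze one chain and return the report dictionary."""
    opts = opts or AnalysisOptions()
    curve, residue_ids = extract_backbone(chain)
    bridges = detect_disulfide_bridges(chain, max_ss_dist=opts.ss_cutoff)
    bridges += detect_ion_bridges(chain, coordination_dist=opts.ion_cutoff)
    if opts.extra_bridges:
        bridges += declare_bridges(chain, opts.extra_bridges)
    chain.bridges = bridges

    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "protknot_version": __version__,
        "chain": chain.source_id,
        "n_residues": len(chain.residues),
        "bridges": [
            {"kind": b.kind, "res_a": b.res_a, "res_b": b.res_b, "mediator": b.mediator}
            for b in bridges
        ],
        "sampling": {
            "n_closures": opts.n_closures,
            "n_directions": opts.n_directions,
            "fingerprint_n": opts.fingerprint_n,
            "seed": opts.seed,
            "direction_set": "fibonacci" if opts.seed is None else "random",
            "ion_coordination_cutoff": opts.ion_cutoff,
            "ss_cutoff": opts.ss_cutoff,
            "max_bridges": opts.max_bridges,
        },
    }

    # ---- probabilistic knots + fingerprint -------------------------------
    do_fp = "fingerprints" not in opts.skip
    if do_fp:
        fp = knot_fingerprint(
            curve,
            residue_ids,
            n_closures=opts.fingerprint_n,
            stride=opts.stride,
            full_n=opts.n_closures,
            seed=opts.seed,
        )
        corner_type, corner_p = fp.cells[fp.whole_chain]
        knot_sec = {
            "dominant": corner_type.name,
            "probability": round(corner_p, 6),
            "fingerprint": {
                f"{s}:{e}": [t.name, round(p, 6)] for (s, e), (t, p) in sorted(fp.cells.items())
            },
            "stride": fp.stride,
        }
        if not corner_type.is_trivial and corner_type.name != "unknown":
            try:
                core = locate_core(fp)
                knot_sec["core"] = {
                    "start": core.core_start,
                    "end": core.core_end,
                    "n_tail": core.n_tail,
                    "c_tail": core.c_tail,
                }
            except TopologyError:
                pass
    else:
        from .probabilistic import knot_spectrum

        sp = knot_spectrum(curve, n=opts.n_closures, seed=opts.seed)
        t, p = dominant_type(sp)
        fp = None
        knot_sec = {"dominant": t.name, "probability": round(p, 6), "spectrum": _spectrum_dict(sp)}
    report["knots"] = knot_sec

    # ---- knotoids --------------------------------------------------------
    kfp = None
    if "knotoids" not in opts.skip:
        globe = projection_globe(curve, resolution=opts.n_directions, seed=opts.seed)
        dist = globe.distribution()
        t, p = dominant_type(dist)
        knotoid_sec = {
            "dominant": t.name,
            "probability": round(p, 6),
            "distribution": _spectrum_dict(dist),
            "globe": [
                [round(th, 4), round(ph, 4), name] for th, ph, name in globe.to_rows()
            ],
        }
        if do_fp:
            kfp = knotoid_fingerprint(
                curve,
                residue_ids,
                n_directions=opts.fingerprint_n,
                stride=opts.stride,
                full_n=opts.n_directions,
                seed=opts.seed,
            )
            knotoid_sec["fingerprint"] = {
                f"{s}:{e}": [t.name, round(p, 6)] for (s, e), (t, p) in sorted(kfp.cells.items())
            }
        report["knotoids"] = knotoid_sec

    if fp is not None:
        labels = classify_entanglement(fp, kfp)
        report["labels"] = {
            "knot": labels.knot_label,
            "knotoid": labels.knotoid_label,
        }

    # ---- deterministic loops ---------------------------------------------
    if "loops" not in opts.skip:
        loops = enumerate_covalent_loops(chain, max_bridges=opts.max_bridges)
        loop_rows = []
        for lp in loops:
            try:
                res = loop_knot_type(lp)
                name = res.knot_type.name
            except TopologyError:
                name = "unknown"
            loop_rows.append(
                {
                    "notation": lp.notation,
                    "knot_type": name,
                    "length_residues": lp.length_residues,
                    "n_bridges": lp.n_bridges,
                }
            )
        report["covalent_loops"] = loop_rows
        report["bridged_paths"] = [
            {"notation": p.notation, "n_bridges": p.n_bridges}
            for p in bridged_open_paths(chain, max_bridges=opts.max_bridges)
        ]

    # ---- cysteine knots --------------------------------------------------
    if "ck" not in opts.skip:
        motifs = detect_cysteine_knots(chain)
        report["cysteine_knots"] = [
            {
                "loop": m.loop_notation,
                "piercing": m.piercing_notation,
                "class": m.ck_class,
                "piercing_sign": m.piercing_sign,
                "multiple_piercing": m.multiple_piercing,
                "nontrivial_cycles": verify_ck_loops_unknotted(m, chain),
            }
            for m in motifs
        ]
    return report
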