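"""End-to-end demo pipeline: simulate -> scan -> fine-map -> classify.

Chains the stages on synthetic populations built around the wheat 7AL
spikelet-number locus: a RIL QTL scan on a three-QTL genome (2BS, 7AS,
7AL), an F2-style recombinant screen of the 7AL window with progeny-tested
recombinant families and constraint-intersection interval deduction, a
haplotype/allele panel with frequency and homogeneity summaries, and an
environments-as-blocks effect table.  Deterministic given the seed; every
stage's random stream is spawned from the run seed.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import finemap as fm
from . import io as hio
from . import popgen, scan, simulate, wheat7al
from .genetics import GenomicInterval, format_width


def _stage_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def run_pipeline(config: dict, out_dir: "str | Path | None" = None) -> dict:
    """Run the full demo pipeline and return the machine-readable summary.

    Aborts with a stage-labeled error if any stage fails.  When ``out_dir``
    is given, writes the genotype/phenotype CSVs, the LOD curve, the
    deduction JSON and the summary JSON there.
    """
    cfg = dict(hio.DEFAULT_CONFIG)
    cfg.update(config)
    seed = int(cfg["seed"])
    rng_scan, rng_fine, rng_panel, rng_pheno = _stage_rngs(seed, 4)
    out = Path(out_dir) if out_dir is not None else None
    summary: dict = {"seed": seed}

    # --- stage 1: RIL population and QTL scan --------------------------
    try:
        gmap = simulate.demo_genetic_map()
        qtls = simulate.demo_qtl_effects()
        pop = simulate.simulate_population(
            simulate.CrossDesign(
                "RIL_self", cfg["n_ril_lines"], gmap, rng_seed=seed,
                ril_generation=cfg["ril_generation"],
            )
        )
        pheno = simulate.simulate_phenotypes(
            pop.genotypes, qtls, reps_per_env=cfg["reps_per_env"],
            rng=rng_pheno,
        )
        line_means = pheno.groupby("line_id")["value"].mean()
        probs = scan.conditional_genotype_probs(pop.genotypes, gmap, "RIL_self")
        curve = scan.hk_scan(probs, line_means)
        peaks = scan.find_peaks(curve, threshold=cfg["lod_threshold"])
        mqm = (
            scan.multi_qtl_fit(peaks, probs, line_means) if peaks else None
        )
        summary["scan"] = {
            "n_lines": pop.genotypes.n_lines,
            "max_lod": curve.max_lod(),
            "peaks": [
                {
                    "chrom": p.chrom,
                    "pos_bp": p.pos_bp,
                    "lod": round(p.lod, 3),
                    "effect": round(p.effect, 3),
                    "pve": round(p.pve, 4),
                }
                for p in peaks
            ],
            "total_pve": (
                round(float(mqm.attrs["total_pve"]), 4) if mqm is not None else None
            ),
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'scan' failed: {e}") from e

    # --- stage 2: fine mapping of the 7AL locus ------------------------
    try:
        region_map = simulate.region_map_7al(include_locus=True)
        region = wheat7al.BXR_INITIAL_WINDOW
        screen_pop = simulate.simulate_population(
            simulate.CrossDesign(
                "F2", 600, region_map,
                rng_seed=int(rng_fine.integers(2**31 - 1)),
            )
        )
        truth_calls = screen_pop.genotypes.calls[simulate.LOCUS_MARKER_NAME]
        observed = screen_pop.genotypes.subset_markers(
            [m.name for m in region_map.markers
             if m.name != simulate.LOCUS_MARKER_NAME]
        )
        screen = fm.find_recombinants(observed, "IWB713", "IWB53096")
        classes = fm.group_by_breakpoint(observed, screen.recombinant_ids)
        region_markers = [
            m for m in observed.markers
            if region.contains_pos(m.chrom, m.pos_bp)
        ]
        families = []
        for cls_lines in classes.classes:
            line = cls_lines[0]
            fam = fm.RecombinantFamily.from_genotypes(
                line, observed.calls.loc[line], region_markers, region
            )
            if fam.het_segment_max is None:
                continue
            het_truth = truth_calls[line] == "H"
            test_pheno = simulate.simulate_progeny_test_phenotypes(
                heterozygous=het_truth, rng=rng_fine,
            )
            result = fm.progeny_test_classify(line, test_pheno, alpha=cfg["alpha"])
            families.append((fam, result))
        het_n = sum(r.classification == "heterozygous" for _, r in families)
        if het_n == 0:
            raise RuntimeError("no heterozygous-classified recombinant family")
        deduction = fm.deduce_locus_interval(
            families, observed.markers, region
        )
        iv = deduction.candidate_interval
        summary["finemap"] = {
            "n_screened": screen.n_screened,
            "n_recombinant": screen.n_recombinant,
            "n_classes": classes.n_classes,
            "n_families_tested": len(families),
            "candidate_interval": {
                "chrom": iv.chrom,
                "start_bp": iv.start_bp,
                "end_bp": iv.end_bp,
                "left_marker": deduction.left_marker,
                "right_marker": deduction.right_marker,
                "width": format_width(iv.width_bp("between_markers")),
            },
            "contains_true_locus": bool(
                any(piece.start_bp <= simulate.DEFAULT_LOCUS_BP <= piece.end_bp
                    for piece in deduction.viable_intervals())
            ),
            "n_alternative_intervals": len(deduction.alternative_intervals),
            "conflicts": deduction.conflicts,
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'finemap' failed: {e}") from e

    # --- stage 3: haplotypes, alleles, frequencies ----------------------
    try:
        snps, truth = simulate.synthetic_snp_panel(rng=rng_panel)
        assignment = None
        from .haplotypes import assign_haplotypes, classify_wapo_allele

        assignment = assign_haplotypes(snps)
        calls = pd.DataFrame(
            {
                "accession": list(truth),
                "group": ["hexaploid"] * len(truth),
                "allele": [
                    classify_wapo_allele(
                        simulate.diagnostics_for_haplotype(truth[a])
                    ).label
                    for a in truth
                ],
            }
        )
        freq = popgen.frequency_table(calls, group_col="group", allele_col="allele")
        summary["haplotypes"] = {
            "group_counts": assignment.group_counts,
            "allele_percentages": {
                col: float(freq.percentages.loc["hexaploid", col])
                for col in freq.percentages.columns
            },
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'haplotype' failed: {e}") from e

    # --- stage 4: effect table ------------------------------------------
    try:
        marker_calls = pop.genotypes.calls["IWA5913"]
        groups = marker_calls.map({"A": "H1", "B": "H2"}).dropna()
        eff = popgen.effect_table(
            pheno, groups, high_level="H2", baseline_level="H1"
        )
        row = eff.table.iloc[0]
        summary["effects"] = {
            "trait": row["trait"],
            "ls_mean_H1": round(float(row["mean_H1"]), 2),
            "ls_mean_H2": round(float(row["mean_H2"]), 2),
            "difference": round(float(row["diff"]), 2),
            "pct_difference": float(row["pct_diff"]),
            "p_value": float(row["P"]),
        }
    except Exception as e:
        raise RuntimeError(f"pipeline stage 'effects' failed: {e}") from e

    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        hio.write_genotype_csv(pop.genotypes, out / "ril_genotypes.csv")
        hio.write_phenotype_csv(pheno, out / "ril_phenotypes.csv")
        curve.table.to_csv(out / "lod_curve.csv", index=False)
        hio.write_json(summary, out / "summary.json")
    return summary
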