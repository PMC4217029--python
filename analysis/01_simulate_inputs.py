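#!/usr/bin/env python
"""Generate every synthetic input the downstream analyses consume.

Produces, under results/: a proteome FASTA with 20 strict- and 30
core-conforming motif sites planted at known positions, a 200-gene
evidence cohort with intended candidate labels, growth matrices built to
each rubric grade, and an LC-MS peak list with 2 ppm mass error — each
with its ground-truth side table.
"""

from pathlib import Path

import pandas as pd

from ypkscreen import evidence as ev
from ypkscreen import scan, sdl, simulate

SEED = 20140901
OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

proteins, truth = simulate.generate_proteome(n_proteins=15, n_strict=20, n_core=30, seed=SEED)
scan.write_fasta(proteins, OUT / "synthetic_proteome.fasta")
pd.DataFrame(
    [
        {"protein_id": s.protein_id, "position": s.position, "strict_conforming": int(s.strict_conforming)}
        for s in truth.planted_sites
    ]
).to_csv(OUT / "synthetic_proteome_truth.tsv", sep="\t", index=False)
print(f"proteome: {len(proteins)} proteins, {len(truth.planted_sites)} planted sites "
      f"({sum(s.strict_conforming for s in truth.planted_sites)} strict)")

cohort = simulate.generate_evidence(n_genes=200, flip_rate=0.0, seed=SEED)
ev.write_evidence(cohort.evidence, OUT / "synthetic_evidence.tsv")
pd.DataFrame(
    [{"gene_id": g, "is_candidate": int(v), "branch": cohort.branches[g]} for g, v in cohort.labels.items()]
).to_csv(OUT / "synthetic_evidence_truth.tsv", sep="\t", index=False)
scan.write_hits(cohort.hits, OUT / "synthetic_evidence_sites.tsv")
print(f"evidence cohort: {len(cohort.evidence)} genes, "
      f"{sum(cohort.labels.values())} intended candidates")

intents = {f"gene_{g.value}": g for g in sdl.SDLGrade}
records, gtruth = simulate.generate_growth_matrices(intents, seed=SEED)
sdl.write_growth_table(records, OUT / "synthetic_growth.tsv")
pd.DataFrame(
    [{"gene_id": g, "intended_grade": gr.value} for g, gr in gtruth.intended_grades.items()]
).to_csv(OUT / "synthetic_growth_truth.tsv", sep="\t", index=False)
print(f"growth matrices: {len(records)} genes, one per rubric grade")

peaks, ptruth = simulate.generate_peaklist(error_ppm_sd=2.0, n_noise_peaks=8, seed=SEED)
pd.DataFrame({"mz": peaks}).to_csv(OUT / "synthetic_peaks.tsv", sep="\t", index=False)
pd.DataFrame(
    [{"species": n, "true_mz": mz, "error_ppm": e} for n, mz, e in ptruth.spiked_species]
).to_csv(OUT / "synthetic_peaks_truth.tsv", sep="\t", index=False)
print(f"peak list: {len(peaks)} peaks ({len(ptruth.spiked_species)} spiked, 8 noise)")
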