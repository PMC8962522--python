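# rinscan

Residue interaction networks, betweenness-centrality hotspot nomination,
mimetic peptide design and binding-isotherm analysis.

## The problem

When a receptor–ligand complex is only available as a modelled structure,
which receptor residue should be mutated to test the interaction? `rinscan`
implements a network-based answer used to nominate the His112 hotspot of the
TrkA receptor for its interaction with the CD44v3 C-terminal region, and the
downstream sequence and binding analyses that follow from such a nomination:

1. **Residue interaction network (RIN).** Nodes are residues; an edge joins
   residues *a*, *b* when the minimum distance over their heavy-atom pairs
   lies in the closed window [2.5, 5.0] Å.
2. **Betweenness-centrality Z-scoring (BCA).** Unnormalised betweenness
   bc(v) = Σ_{s<t} σ_st(v)/σ_st is standardised within one structure,
   z(v) = (bc(v) − mean bc)/sd bc, and residues with **z ≥ 2** are called
   *central*.
3. **Differential candidate criterion.** A receptor residue is nominated
   when it is (i) at the receptor/partner interface, (ii) central in the RIN
   of the whole complex, and (iii) *not* central in the receptor-alone RIN.
4. **Zone scanning and peptide design.** A variant-exon sequence is cut into
   contiguous zones of roughly equal length (remainder to the C-terminal
   zones — the 42-mer CD44v3 exon splits 10/10/11/11); each zone is a
   candidate mimetic peptide, with scramble controls, deletion constructs
   and point mutants.
5. **1:1 binding isotherm.** Titrations (e.g. microscale thermophoresis)
   are fitted with R([L]) = r_free + (r_bound − r_free)·[L]/(Kd + [L]) by
   bounded nonlinear least squares, with a binding verdict based on fitted
   amplitude vs residual noise.

It is aimed at structural bioinformaticians who want these steps as a
tested, scriptable library and CLI rather than a chain of GUI tools.

## Worked example

Generate the bundled two-chain toy complex whose contact graph is a 6-node
star (receptor chain A: a center and two leaves; partner chain B: three
residues contacting only the center), then run the candidate nomination:

```text
$ rinscan simulate structure --kind star --out star.pdb
6 residues -> star.pdb
$ rinscan candidates star.pdb --receptor-chains A --partner-chains B --out-prefix report
candidates: A:2:HIS
$ cat report_complex_centrality.tsv
# z_threshold: 2.0
# sd_mode: sample
residue	bc	z	central
A:1:GLY	0	-0.408248	False
A:2:HIS	10	2.04124	True
A:3:GLY	0	-0.408248	False
B:1:ASP	0	-0.408248	False
B:2:ASP	0	-0.408248	False
B:3:PHE	0	-0.408248	False
```

The center carries all 10 leaf-pair shortest paths (bc = C(5,2) = 10),
z = 5/√6 ≈ 2.041 ≥ 2 in the complex, but only z ≈ 1.155 in the receptor-alone
path graph — so it alone satisfies the differential criterion, mirroring the
logic that singled out His112.

Sequence and binding stages:

```text
$ rinscan zones STSSNTISAGWEPNEENEDERDRHLSFSGSGIDDDEDFISST
zone 1	1-10	STSSNTISAG
zone 2	11-20	WEPNEENEDE
zone 3	21-31	RDRHLSFSGSG
zone 4	32-42	IDDDEDFISST
$ rinscan simulate titration --kd 9.47 --conc 0.1,0.5,1,3,9.47,30,100,300,1000 \
      --noise-cv 0.02 --seed 11 --out tit.tsv
9 points, Kd=9.47 nM -> tit.tsv
$ rinscan bind fit tit.tsv
Kd = 9.91881 nM (95% CI 9.33066-10.507); binds: True
```

The fitted Kd recovers the generating value within the 2% multiplicative
noise, and the 95% confidence interval covers it.

## Library surface

```python
from rinscan import (
    load_structure, build_rin, ContactParams,
    betweenness_centrality, centrality_zscores, differential_candidates,
    split_zones, scramble_peptide, global_align, percent_identity,
    fit_binding_isotherm, simulate_binding_series,
)
```

See `docs/methods.md` for the model assumptions, parameter conventions and
known limitations.
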