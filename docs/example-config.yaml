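# Example experiment configuration for `gsindex run-experiment --config ...`
# Values shown are the package defaults (the standard simulated design).

mode: simulate            # "simulate" or "real"

genome:
  n_chromosomes: 10
  markers_per_chromosome: 250
  n_qtl: 315
  n_le_qtl: 15            # QTL simulated in linkage equilibrium with markers
  marker_frac: 0.0906     # recombination fraction between adjacent markers
  qtl_marker_frac: 0.0    # QTL to its left flanking marker

qtl_counts: [300, 100, 60, 40]          # QTL per trait
corr_targets: [-0.5, 0.4, 0.3, -0.3, -0.2, 0.1]  # upper triangle, row order
heritabilities: [0.4, 0.6, 0.6, 0.8]    # per-plot h^2
weights: [1.0, -1.0, 1.0, 1.0]          # economic weights w (net merit H = w'a)

n_genotypes: 500
n_reps: 4                 # plots per genotype
p_selected: 0.10          # top fraction intercrossed (k = 1.755)
l_psi: 4.0                # years per phenotypic selection cycle
l_gsi: 1.5                # years per genomic selection cycle
n_cycles: 7               # selection cycles after the base cycle
seed: 0

arch_tol: 0.05            # tolerance of the architecture calibration search
arch_max_moves: 10000

# real mode only: per-cycle marker tables (cycle 0 = training first) and the
# cycle-0 phenotype table; marker coding "auto", "zero_one_two" or
# "minus_one_one"
marker_paths: []
phenotype_path: null
coding: auto
trait_names: null         # e.g. [GY, PHT, EHT, AD]

outdir: null              # write per-cycle TSVs, matrices and a report here
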