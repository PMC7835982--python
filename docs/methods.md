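# Methods

## Scope and model

`secretonet` re-implements, as a reusable and fully tested pipeline, a
secretome-to-mediator analysis: catalog the proteins of a conditioned medium
(CM) by target-decoy-filtered LC-MS evidence, quantify treatment responses of
measured factors (multiplex cytokines, qPCR genes), summarize flow-cytometry
subpopulations, and integrate everything on a protein–protein interaction
network to select hub mediators. Wet-lab steps, spectrum searching, and
figure-level significance testing are out of scope; the pipeline starts from
scored PSM tables and interaction records in BioGRID TAB 2.0 layout.

## Proteomics stage

*FDR threshold.* The threshold is the smallest observed score `t` with
`#{decoy PSMs ≥ t} / #{target PSMs ≥ t} ≤ α` (default α = 0.01). The plain
decoy/target ratio is used rather than q-value interpolation: it is the
minimal faithful reading of "1% FDR" and makes the estimator exactly
testable against a brute-force scan over every observed score. If no cutoff
reaches the level the threshold is +∞ and nothing is accepted. The unit of
FDR control is the PSM by default; `fdr_unit="peptide"` collapses records to
the best score per normalized peptide before estimating the threshold, since
the original level of control is ambiguous in such reports.

*Acceptance.* A protein is accepted when ≥ 2 distinct peptide sequences pass
the threshold (configurable). "Distinct" means distinct after uppercasing
and stripping everything that is not a residue letter (mass tags, `(ox)`
marks, terminal annotations) — the conventional reading of "unique peptide
sequences". Peptides shared by several proteins count toward each of them
(no razor-peptide assignment); PMSS is the sum of above-threshold target PSM
scores per protein, so removing one passing PSM lowers PMSS by exactly its
score. When a `mode` column is present (CID/ETD spectra scored separately),
thresholds are estimated per mode and records pooled after filtering.

## Expression stage

Cytokine fold changes are ratios of arithmetic replicate means on the
concentration scale; qPCR uses the ΔΔCt method on the Ct scale with
RF = 2^−ΔΔCt — each assay's convention. A Welch t-test (on log
concentrations, or on per-replicate ΔCt values) supplies an optional
p-value. The differential criterion is |log2FC| ≥ 1 by default, boundary
inclusive, optionally AND-combined with p ≤ threshold; the original report
never states its criterion for "differentially expressed", so a reproducible
fold-change rule with a configurable cut was chosen — the network stage
consumes the call as a set either way. Fold changes are reported on both
log2 and linear scales. Differential calls are pooled across subtypes before
the network stage (a factor differential in any subtype counts once).

## Cytometry stage

Fixed-threshold rectangular gating: 7-AAD < threshold (viability), CD68 ≥
threshold (macrophage pre-filter), then assignment to exactly one of the
eight CD163±/CD206±/CD80± combinations by per-channel comparison (≥ means
positive). The eight combos partition the classified events, so percentages
close to 100 by construction. No compensation, doublet handling, or
hierarchical gating — the original gating strategy is unreported, so
thresholds are plain configuration and the synthetic generator plants
components far enough apart (five log-SDs from the default threshold of
1000 a.u.) that results are insensitive to the exact cut.

## Network stage

BioGRID TAB 2.0 parsing uses official symbols, tolerates header lines,
drops self-interactions and malformed lines with log entries, and filters by
taxon (default 9606) and optionally by experimental system type; both
physical and genetic interactions are kept by default. An
accession↔symbol mapping table joins the LC-MS namespace to the network
namespace; ambiguous 1→many mappings resolve to the lexicographically first
symbol, deterministically, with a warning.

Construction follows the three-step design: CM–CM edges first (both
endpoints catalogued, deduplicated, undirected); then edges from network
proteins to differentially expressed measured factors, with factors absent
from both catalogs entering as new nodes; edges between two panel members
are excluded by default (`include_panel_panel_edges` restores them) since
the procedure anchors every retrieval step on CM proteins. `measured_degree`
counts *distinct* differential factors adjacent to a node and is stored
separately from total degree (the figure's font-size attribute), because the
two are easily conflated. Candidates are nodes unique to the CM or panel
members; selection requires measured degree ≥ 6 — the strict reading of
"more than five measured factors" — with the cutoff configurable. Ranking is
measured degree descending, ties lexicographic. Exports: GraphML (node
attributes typed), SIF, and node/candidate TSVs.

## Synthetic data and planted truth

The generator emulates the study conditions: 60 CM-only, 20 shared and 20
control-only proteins; 2 planted hubs; a 40-analyte cytokine panel over six
macrophage subtypes (M0, M1, M2, M2a, M2b, M2c) with n = 4 replicates; a
4-gene qPCR panel (PDGFB, TIMP1, PTGS2, MRC1) plus 18S as housekeeping;
40,000 cytometry events with 10% non-viable. Planted fold changes mirror the
reported direction of response (cytokines down in M1, up in M2/M2a, …) with
magnitudes ≥ 1.5 log2 units for differential features — ≥ 3 propagated
standard errors from the |log2FC| ≥ 1 cut at default noise, so differential
calls are stable — and one deliberately sub-threshold effect (TIMP1, +0.3)
to exercise the negative path.

Scores: targets ~ Normal(30, 5), decoys ~ Normal(12, 5), decoy fraction 0.3.
The planted "true" threshold solves `d·S_d(t)/((1−d)·S_t(t)) = α`
analytically and is recorded in the truth sidecar; every generated protein
receives two guaranteed above-threshold peptides so the two-peptide rule is
satisfiable by construction. Noise: multiplicative log-normal with CV 0.15
for concentrations (they must stay positive), additive Gaussian with SD 0.15
cycles on Ct — magnitudes are conventions typical of the assays, since the
original report gives none.

Hub wiring: each planted hub connects to at least `hub_min_measured_degree
+ 3` differential panel members (at least 9 of the 17 planted differential
features), every non-hub CM protein to at most 5, a ring plus random
background edges connect the CM proteins, and a few distractor edges involve
proteins outside every catalog. Hubs are drawn from the CM-only proteins:
the selection rule only admits proteins unique to the CM or panel members,
so a hub planted on a shared protein would be unselectable by design. With
these defaults the set {protein : measured degree > 5} equals the planted
hub set exactly, which the acceptance suite verifies across 100 seeds.

What the generator does **not** emulate: realistic peptide/spectrum
properties, interactome topology of a real BioGRID release, cytometry
spillover, or between-replicate correlation. Passing tests therefore show
the *procedure* is correct under its stated model, not that the original
biological findings reproduce — those depend on unreleased LC-MS data and an
unnamed BioGRID release and are explicitly not desk-reproducible.

## Numerical choices and degenerate inputs

- Every generator is a pure function of `(seed, config)` via per-stream
  `numpy` Generators; identical configs give byte-identical files.
- FDR threshold candidates are the observed scores only; ties at the
  threshold are accepted (`≥ t`).
- Empty PSM tables yield empty catalogs with a warning; an unreachable FDR
  level yields +∞ and zero acceptances; a table with no decoys is an error.
- Fold changes require both conditions present and positive means; missing
  cells raise instead of propagating NA.
- Percentages are exact fractions of the classified-event count; an empty
  gate yields all-zero percentages rather than NaN.
- Problem sizes in the test and acceptance runs (30–100 synthetic studies,
  ≤ 200-row PSM tables, ≤ 50-node random graphs, 40,000-event cytometry)
  were chosen so each property is sharply testable while the whole suite
  runs in about a minute.

## Known limitations

- The decoy/target ratio estimator is conservative-but-simple; it does not
  produce per-PSM q-values.
- Protein inference stops at the two-peptide rule; shared-peptide parsimony
  is out of scope.
- The Welch-test option assumes independent replicates; paired designs are
  not modeled.
- FCS binary input is not supported; events arrive as TSV tables.
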