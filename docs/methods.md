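# Methods

This note documents the models, defaults and design choices behind
`metexpand`, and what the synthetic benchmark does and does not show.

## Mass arithmetic

Monoisotopic masses come from a static IUPAC most-abundant-isotope table
embedded in `metexpand._masses` (≥ 6 decimals; H 1.007825032,
C 12 exactly, N 14.003074005, O 15.994914620, P 30.973761998,
S 31.972071174, plus Na, Cl, F, K). No online lookup is ever performed,
so results are deterministic and reproducible offline.

Singly charged adducts use the **electron-corrected proton mass
1.007276 Da** rather than the neutral-hydrogen 1.007825: the species
observed in the spectrometer is an ion, and the electron-corrected value
is what reproduces published 4-decimal precursor m/z values for
protonated/deprotonated metabolites (e.g. 256.2635 for C₁₆H₃₃NO [M+H]⁺,
195.0510 for C₆H₁₂O₇ [M−H]⁻). Only |z| = 1 adducts are supported;
[M+H]⁺, [M−H]⁻, [M+Na]⁺, [M+NH₄]⁺ and [M+Cl]⁻ are registered, with the
proton adducts as the per-mode defaults. Multiply charged species and
isotope-pattern scoring are out of scope.

### Formula decomposition

`decompose_mass` enumerates every composition within per-element bounds
whose adduct m/z lies inside the tolerance window, by depth-first search
over elements in decreasing mass order with two prunings: a branch is cut
when its accumulated mass overshoots the window, or when the maximum mass
still reachable cannot bridge the gap; for the final (lightest) element
the admissible count interval is computed directly. The search is
provably exhaustive within bounds — the test suite checks exact agreement
with an independent nested-loop enumeration on random targets.

Plausibility filters: RDBE `1 + Σ n_e(v_e − 2)/2 ≥ 0` with lowest common
valences (for CHNO this is the Senior bound H ≤ 2C + N + 2) and H/C
∈ [0.1, 6], applied only when carbon is present so that e.g. water
remains decomposable. Default bounds scale with the target mass
(`default_bounds`: each element capped by mass/atomic-mass, hydrogen by
the Senior maximum). Results are sorted by |ppm error| with ties broken
by Hill-string order, so output order is reproducible. Degenerate
inputs: targets outside (0, 5000] are errors; an empty result is a valid
answer, not an error.

## Dereplication and MSI levels

The selection cascade mirrors the MSI confidence hierarchy: any passing
spectral-library match gives level 2; otherwise a compound-table
exact-mass hit gives level 3; otherwise a successful formula
decomposition gives level 4; otherwise the feature is a level-5 spectral
feature. Level 1 is never assigned automatically — it requires an
authentic standard. Within a source the highest score wins; ties break
on compound id. Because exactly one selected candidate exists per
feature, per-level counts always form an exhaustive disjoint partition
of the feature list, which the ledger asserts on every run.

### Spectral score and its threshold

Peaks are weighted by √intensity and paired greedily (largest weight
product first, one use per peak) within the fragment tolerance
(default 0.01 Da). The reported score is

    (Σ matched w_q w_r)² / (Σ w_q² · Σ w_r²),

i.e. the **square** of the conventional spectral cosine — 1.0 iff the
matched parts are proportional and complete (Cauchy–Schwarz), symmetric,
invariant under uniform intensity rescaling. The square makes partial
overlap penalties steeper than the plain cosine.

Because the scale is squared, the default acceptance threshold
`min_score = 0.50` corresponds to a conventional cosine of ≈ 0.71, the
usual library-match cutoff in spectral-search practice. Setting 0.70 *on
the squared scale* (cosine 0.84) was considered and rejected: at the
generator's default 20 % peak dropout it rejects roughly half of
genuinely matching spectra, which mismeasures the matcher rather than
the noise. Both the threshold and the minimum matched-peak count
(default 3) are configuration knobs.

Other defaults: precursor tolerance 10 ppm (Orbitrap-class accuracy with
margin; published deviations on comparable instruments reach ~10 ppm),
retention time is carried through but never used for matching (the
dereplication is mass/spectrum based). Candidates whose neutral mass
exceeds the precursor-implied mass by > 0.5 Da are flagged
`in_source_suspect` — a hint that an in-source fragment was selected as
precursor — but are not removed.

## Suspect-list curation

Structure identity uses the standard InChI when available, else
canonical SMILES, both derived via RDKit; this merges records across
databases with heterogeneous notation while keeping constitutional
isomers separate. Rows with neither an identifier nor a structure are
discarded (counted), rows whose structure fails to parse are quarantined
into a machine-readable rejects report — the discard rule stays
auditable. Deduplication unions names/synonyms/sources/species
(order-preserving, so provenance is conserved) and keeps the smallest
id; it is idempotent. Chemical classification is attached from a static
structure-key → (superclass, class, subclass) map file; live ontology
services are out of scope, and non-empty levels must form a prefix of
the hierarchy.

## Similarity network

Fingerprints are radius-2, 2048-bit achiral Morgan (ECFP4-like) —
community defaults, configurable. Tanimoto is computed bit-parallel on
packed arrays and verified against the set-based definition and against
RDKit's implementation. Edges require similarity ≥ 0.85 by default;
isolated nodes are retained so class overlays cover the full catalog;
clusters are plain connected components (no community detection).
Raising the threshold can only remove edges (anti-monotone), and the
edge set is invariant under record order.

A consequence worth knowing: radius-2 achiral fingerprints genuinely
collide for saturated-chain homologs (octanoic vs. decanoic acid share
every local atom environment) and for stereoisomer sugars. "Tanimoto
= 1" intersection therefore conflates such pairs; `match_common` offers
a strict mode that additionally requires identical structure keys.
Default is the fingerprint-faithful mode.

## Union catalog and curation

`build_union` assigns origins (`suspect` / `common` / `novel`) from the
Tanimoto-1 pairing and satisfies inclusion–exclusion exactly
(`n_union + n_pairs = n_suspects + n_annotated`). Manual curation is
mechanized as a declarative blocklist (regex on name, structure key or
source tag); every removal is logged with the matching rule and reason,
application is idempotent, and an empty pattern is a configuration
error — so catalog reductions are reproducible and fully audited.

## Synthetic studies

The generator emulates a two-mode DDA acquisition over ~115 embedded
template metabolites (CHNOPS only, four dominant superclasses of algal
metabolomes, default sampling weights 0.35/0.25/0.22/0.18). Fragments
are *pseudo-fragments*: hash-seeded sub-masses of the precursor,
identical between a compound's library spectrum and its query feature.
This isolates the matching machinery; it does **not** emulate real
fragmentation chemistry, isotope envelopes, adduct mixtures,
chromatographic peak shape or in-source fragmentation — so passing
benchmarks demonstrate correct bookkeeping and matching under the stated
noise model, not annotation accuracy on real spectra.

Noise defaults: 5 ppm m/z jitter (uniform), 10 % spurious peaks
(binomial, uniform over the scan range), 20 % peak dropout; scan range
80–1,200 m/z; 8–14 peaks per spectrum. Decoy features get precursors
rejection-sampled in 80–400 m/z until no bounded CHNOPS formula explains
them at the annotation tolerance — this simultaneously guarantees
expected level 5 and no accidental library/table precursor hit (any hit
would itself decompose).

In strict mode (default) study compounds are pairwise distinct in
fingerprint and separated by ≥ 3 precursor-tolerance windows in mass, so
expected MSI levels, structures and origins are exact under zero noise;
non-strict mode lifts both constraints to allow studies larger than the
template set (templates repeat under fresh ids) at the price of
occasionally ambiguous exact-mass ground truth. Everything is driven by
one integer seed; equal seeds give byte-identical artifacts.

## Benchmark problem sizes

The test suite runs a 30-compound/33-feature zero-noise study (exact
ground-truth recovery), a 195-compound/200-feature default-noise study
(top-1 structure recovery ≥ 90 %; measured ≈ 95 % at seed 42), 200
random decomposition targets against the brute-force oracle, full
round-trip recovery over all plausible formulas within
{C ≤ 10, H ≤ 20, N ≤ 2, O ≤ 4}, 1,000 random Tanimoto pairs against the
set oracle, 50 random union catalogs for the counting identities, and a
1,997-record catalog with a 27-rule blocklist (→ 1,970 records, complete
audit log).

## Known limitations

* No fragmentation-tree or machine-learned class prediction; chemical
  classes come from a supplied map, otherwise records stay unclassified.
* Exact-mass lookup cannot distinguish isomers; ties are broken
  deterministically by id, not chemically.
* Hashed-fingerprint Tanimoto = 1 is necessary but not sufficient for
  structure identity (see strict mode).
* mzML/RAW parsing is out of scope; the pipeline starts from peak-picked
  MGF/MSP.
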