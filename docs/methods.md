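# Methods

## The model

`ddrsim` simulates a single mammalian cell in G1 as a continuous-time Markov
jump process over 18 molecule types. Three coupled layers:

**DNA damage and NHEJ repair.** The genome is coarse-grained into 50
independent DNA sites (`DNA(id~1..50, site~ok~sdsb~cdsb, h2ax~u~p~foci)`).
Reactive oxygen species (ROS) break intact sites — usually a simple
double-strand break (sdsb), occasionally a complex one (cdsb) — and can
escalate an existing sdsb to cdsb (oxidative attack on open ends).
Irradiation is an instantaneous scheduled event: each intact site is hit
with probability `1 − exp(−y·D/50)` for dose `D` (Gy) and DSB yield `y`,
and a hit is complex with probability `fc_max·D/(D + fc_half)`,
non-decreasing in dose. Repair proceeds through two pathways sharing the
broken site:

* D-NHEJ: Ku70/80 binds the break, recruits DNA-PKcs, which
  autophosphorylates and recruits ligase IV; ligation restores the site.
  Ku carries a redox-sensitive cysteine: ROS oxidizes site-bound Ku,
  raising its dissociation rate and destabilizing Ku–DNA-PKcs complexes
  (oxidized complexes can fall apart), so high ROS slows the fast pathway.
* B-NHEJ: PARP-1 binds the break and recruits ligase III; both binding and
  ligation are slower, and complex breaks ligate more slowly than simple
  ones in both pathways.

**Damage foci.** Active ATM (or autophosphorylated DNA-PKcs in the
complex) phosphorylates H2AX at a broken, factor-bound site; an active ATM
molecule then binds p-H2AX and the focus matures (`h2ax~foci`). Focus
resolution disassembles to p-H2AX and releases ATM, independent of repair:
a focus can resolve while the break persists (and re-form), and a focus
can outlive a repaired break. Ligation, however, fires only when the site
has both a complete repair complex and a formed focus. Both constraints
are enforced structurally in the state machine and checked against the
exact event log in the tests.

**Signalling and senescence.** Damage activates a well-mixed ATM pool
(activation propensity proportional to the number of broken sites).
Active ATM phosphorylates p53 (protecting it from MDM2-mediated
degradation) and MDM2 (destabilizing it). p53 above a threshold switches
MDM2 transcription high; the mRNA delay plus MDM2 turnover make the
p53–MDM2 negative feedback a relaxation oscillator that pulses while ATM
stays active and returns to a stable low state once damage is repaired —
pulse number tracks damage level while amplitude and period do not
("digital" behaviour). p53 above a lower threshold also switches on p21
(`P()`) transcription; because that switch saturates well below typical
pulse peaks, the slow p21 pool (mRNA and protein lifetimes of hours)
integrates the *duration* of p53 elevation rather than its amplitude.
p21 drives the senescence counter `Sen(int~1..10)`: above a p21 threshold
the counter steps up (PLUS), below it steps down (MINUS), and reaching 10
switches the cell irreversibly to `State~sen`. Very high sustained p21
also switches GADD45 production high, which raises ROS production — the
positive feedback (p21 → GADD45 → ROS → more breaks and oxidized Ku →
more p53/p21) that commits cells to senescence and keeps damage foci
persistent afterwards. After the switch, free Ku and PARP are degraded
toward senescent floor levels and Ku's binding rate drops, further slowing
repair.

The p38 molecule is declared and carried at a fixed phosphorylation level;
the ROS feedback is routed through GADD45 alone. This keeps the molecule
inventory faithful while avoiding a redundant second feedback arm.
p21's protein is the `P()` molecule of the inventory.

## Simulation algorithm

The engine is network-free: the 50 DNA sites are explicit agents with a
small per-site state machine (break type × H2AX/focus status × bound
factors), everything else is a well-mixed count. Every event executes the
exact direct-method SSA: all propensities are recomputed from state, a
channel is selected, and the state is mutated. Scheduled protocol events
(irradiation, Nutlin factor changes, ROS-multiplier changes) truncate the
next-reaction time and are applied atomically, which is exact for
piecewise-constant propensities. Randomness comes from a self-contained
xorshift64\* generator seeded by splitmix64, so a (model, protocol, seed)
triple reproduces bit-identical trajectories. The kernel is compiled with
numba; an 84-hour irradiated cell takes on the order of a second.

The same rule set, written in a small BioNetGen-style dialect, is expanded
by `ddrsim.network.enumerate_network` into the concrete reaction network
(4,583 species, 22,341 reactions at 50 sites) by breadth-first
reachability; a plain Gillespie simulator over the expanded network serves
as an independent cross-check of the compiled kernel on reduced models.

Nutlin-3 is a piecewise-constant factor in [0, 1] multiplying the p53–MDM2
association (1 = no inhibition, 0 = complete block); the default regimen
blocks completely from the irradiation time onward.

## Observables and conventions

* All times are minutes; all abundances are molecule counts per cell.
* The p53 readout for every analysis is total p53 (phosphorylated +
  unphosphorylated), matching total-fluorescence measurements.
* The focus count is the number of sites with a matured focus; focus
  lifetimes are read from the exact event log, not the sampling grid.
* The sampling grid defaults to 5 min, resolving 350–600 min pulses with
  <2% width quantization.
* Senescence is called from the Sen state flag. Default horizons: 84 h
  after irradiation for dose–response studies, 30 h from the start for
  background-ROS studies.

## Pulse detection

The reference pulse definition from the original imaging studies is not
precisely specified, so the detector is defined here and frozen: the trace
is smoothed with a 30-min moving average (edge-replicated), the baseline
mean and SD are estimated from the pre-perturbation window, and peaks are
found above `mean + 2·SD` with prominence of at least 6 baseline SDs.
A pulse's amplitude is its peak height above the baseline mean; its width
is the span above the half-amplitude level (relative to baseline),
truncated at inter-pulse valleys. This baseline-referenced width is what
makes a pulse train with short dips report widths close to the pulse
period, which is the regime the population statistics describe. Both
thresholds and the smoothing window are exposed; the defaults were tuned
once against the published population statistics and then frozen.
Dispersions are sample SDs (n−1); CV = SD/mean of the pooled pulses.

## Parameters

Rate constants live in one structured file per preset
(`src/ddrsim/presets/*.yaml`, sections molecules/rules/functions/
parameters) with units and a provenance tag: `original-NHEJ`,
`original-senescence`, `merged` (composite of merged two-step reactions),
`new` (introduced at the integration seams), or `calibrated`. The
published model's full rate table is not reproduced in the main text, so
the numeric values here were calibrated against the printed population
statistics (network size; baseline homeostasis; pulse width/timing;
senescence dose–response and fractionation; the 10× ROS response); the
provenance tags record which constants are conceptually inherited versus
newly fitted. The calibration used the package's own summary-loss
machinery (common random numbers, derivative-free search) with several
hundred model evaluations per stage — first the oscillator timescales
against a deterministic caricature, then the stochastic pulse statistics,
then the senescence arm with the pulse side frozen.

Parameters that matter most (units: 1/min unless noted):

* `dsb_yield` (breaks/Gy): converts dose to expected breaks over the 50
  sites; with `fc_max`, `fc_half` it sets the initial sdsb/cdsb mix.
* `k_atm_act` (per broken site per ATM): damage sensing gain; with
  `k_atm_deact` it sets how many breaks keep the ATM pool switched on.
* `theta_p53_mdm2` (molecules): the MDM2 transcription relay threshold —
  the pulse ceiling; mRNA decay (`k_mdm2_mrna_dec`) is the loop delay that
  sets the ~8 h pulse period.
* `theta_p53_p21` (molecules): the saturating p21 switch; lies well below
  pulse peaks so p21 integrates elevation time.
* `k_sen_plus`, `k_sen_minus`, `theta_p21_sen`: the counter's drift rates
  and gate; these map hours-above-threshold to commitment probability.
* `theta_p21_gadd`: the ROS-runaway gate; set near the p21 plateau so only
  sustained multi-pulse signalling triggers the positive feedback.
* `k_ku_ox` (per ROS per molecule): redox impairment of D-NHEJ; the main
  route by which high ROS slows repair.
* `ku_floor`, `parp_floor` (molecules), `k_ku_dep`, `k_parp_dep`:
  post-senescence depletion targets and kinetics.

Presets: `MRC5` is the reference calibration; `MCF7` differs only in the
p21→senescence accumulation rate (`k_sen_plus`), reflecting that cell
line's greater senescence resistance; `high_p53` jointly rescales p53
production and degradation (and the p53-read thresholds) so the
unirradiated p53 level is ~4× higher while downstream senescence
behaviour is preserved.

## Synthetic fixtures

`ddrsim.fixtures` generates inputs with known ground truth for the
analysis stages: p53 traces as a constant baseline plus non-overlapping
triangular or gaussian bumps with iid gaussian noise, and per-site focus
event logs with prescribed lifetimes and censoring. These emulate the
*shape* and the schemas of simulator output, not the mechanistic
correlations between ROS, foci and p53 — so tests built on them verify the
detector and the survival analysis, and say nothing about the simulator's
biology (that is what the engine-level and acceptance tests are for).

## Numerical choices

* Exact SSA throughout; no tau-leaping. Propensities are recomputed fully
  per event (a few hundred arithmetic operations), trading peak speed for
  simplicity and auditability.
* Timed events interrupt the SSA clock (exact for piecewise-constant
  propensities); the irradiation draw consumes the same RNG stream so the
  whole trajectory is seed-reproducible.
* Kaplan–Meier and log-rank use lifelines with the standard tie
  convention (censoring after deaths at tied times). Uncensored KM equals
  the empirical survival function exactly.
* Binomial CIs are exact Clopper–Pearson. Chi-square is Pearson without
  continuity correction.
* The calibration optimizer is bounded Nelder–Mead on a stochastic
  objective with common random numbers; the evaluation log is retained and
  the returned point is never worse than the initial one.
* Degenerate inputs: all-censored survival input warns and returns the
  constant-1 curve; empty trajectory sets, empty groups and zero expected
  counts raise typed errors; a zero-rate model advances its clock without
  events.

## Study-condition defaults

Simulations follow the study design: unirradiated runs last 30 h;
irradiated runs equilibrate 3 h before the pulse and continue 84 h after
it (the senescence horizon is measured from irradiation). Populations are
independent replicates with consecutive seeds. Desk-scale population
sizes (30–50 cells per condition in the tests, ~30–120 in the acceptance
script) were chosen so each statistic's sampling error is small against
its published dispersion; they are the package's own defaults and can be
raised freely.

## Known limitations

* No cell cycle, replication-born damage or homologous recombination: the
  model is a G1/arrest model, and predictions much beyond 48 h should be
  read with caution (deep-senescence processes are out of scope).
* No telomere-associated persistent foci; all sites repair by the same
  rules, so very-long-tail focus persistence arises only from the
  ROS/depletion feedback.
* No apoptosis: the only modelled fate is early senescence.
* The spatial structure of damage is ignored: 50 exchangeable sites with
  a dose-dependent complex-break fraction stand in for track-structure
  dosimetry.
* The p21/ROS feedback is a two-level switch (threshold rate functions),
  not a graded dose–response; this is faithful to the conditional-rate
  formalism the model family uses but makes single-cell commitment more
  switch-like than graded signalling would.
* Several rate constants are calibration-identified only in combination
  (e.g. the counter rates and their threshold); the provenance tags mark
  them, and the calibration module exposes exactly these for refitting.
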