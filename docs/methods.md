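# Methods

## The model

`bisir` implements an SIR/SIS contagion with two immunization channels and
simple demography. Vaccination multiplies the per-contact infection rate by
$(1-\delta)$ for every susceptible; clinical treatment multiplies the
recovery rate by $(1+\lambda)$ for every infected. Susceptibles flow in at
rate $bN$ and every compartment experiences the same natural per-capita
death rate $d$ (there is no disease-induced mortality and no separate
mortality parameter). Network structure enters only through the degree
distribution $p(k)$: all analytic formulas use either $\langle k\rangle$
(homogeneous networks) or $\langle k^2\rangle/\langle k\rangle$
(heterogeneous networks) as a single connectivity factor.

The reference parameter set used throughout the examples and tests is
$b=0.08$, $d=0.05$, $\beta=0.175$, $\gamma=0.05$, $\delta=0.2$,
$\lambda=0.3$, $\langle k\rangle=4$; all rates are per unit time (one
Monte-Carlo step = one unit). Degree distributions are finite truncated
supports; infinite supports are not modelled, since every formula is a
finite sum over $p(k)$.

## Mean-field layer

Two systems are integrated with LSODA (adaptive, stiff-capable,
`rtol=1e-10`, `atol=1e-12`) and reported on a uniform grid: the scalar
homogeneous system and the degree-structured system coupled through
$\Theta = \langle k\rangle^{-1}\sum_k k\,p(k) I_k$. A point-mass degree
distribution makes the two coincide exactly, which the tests exploit.

Newborn handling has two modes. In SPES ("newborns participate") the
inflow $bN$ feeds the transmitting susceptible class, and with $R_0>1$ the
system reaches an endemic equilibrium. In SNES ("newborns do not
participate") the inflow accumulates in a passive pool $P$ with
$\dot P = bN - dP$; $P$ is included in the *reported* $S(t)$ but never in
the infection term, so the epidemic always burns out while the
total-population law $T(t) = bN/d + (T_0 - bN/d)e^{-dt}$ remains identical
to SPES. Reported densities are **not** renormalized by the current
population, so $S(t)$ may exceed 1 while the population grows toward
$b/d = 1.6$; renormalizing by $T(t)$ would be the alternative convention.

## Thresholds layer

The endemic state is found through the self-consistency residual
$F(\Theta)$ of the infected-edge fraction: $F(0)=0$, $F$ is convex, and a
nontrivial root exists iff $F'(0) = 1 - R_0 < 0$. The root is located by
bracketed bisection (no derivatives) to $|F| < 10^{-12}$-level accuracy;
uniqueness follows from convexity. The bracket is $[10^{-12}, 1]$ in the
bounded-density regime $bN < \gamma(1+\lambda) + d$, where $F(1) > 0$ is
guaranteed. Outside that regime the stationary population $bN/d$ can exceed
one, per-class densities (and hence $\Theta^\*$) can exceed one, and the
bracket is widened to the a-priori bound
$\Theta^\* \le bN/(\gamma(1+\lambda)+d)$ that follows from the endemic
$I_k^\*$ expression. The regime label is "critical" when
$|R_0 - 1| \le 10^{-9}$, since exact equality is measure-zero.

$R_0$ diverges as $d \to 0$ (its denominator is $d^2 + \gamma d(1+\lambda)$);
all equilibrium and threshold operations therefore require $d > 0$ rather
than extrapolate. The threshold $\beta_c$ is infinite when $\delta = 1$ or
$b = 0$, and those inputs are rejected.

## CTMC layer

The chain lives on the infected count $i \in \{1..N\}$ with infection rate
$\rho(s,i) = (s/N)\beta i(1-\delta)C$ and recovery rate
$\mu(i)=\gamma i(1+\lambda)$. Two boundary conventions deliberately
coexist, and each operation declares which it requires:

* **Reflected** (matrix artifacts $P$, $Q$, $\pi$, embedded chain): state
  $i=1$ has no recovery exit, and the susceptible argument follows the
  fixed-start indexing $\rho(s_0-i+1, i)$ — $s_0$ (default $N-1$) minus the
  infections already booked, not a live state variable. This asymmetry
  (the recursion shifts $s$ inside $\rho$ but not inside $\mu$) is part of
  the printed chain definition and is implemented literally.
* **Absorbing** (Gillespie simulator): live $(s, i)$ bookkeeping; $i=0$
  ends the epidemic.

Births and deaths do not enter the chain at all — it is two-event by
construction, which is also why the simulator comparison against the mean
field uses the reduced $b=d=0$ ODE.

The stationary distribution is computed from the detailed-balance recursion
$\pi_{i+1}/\pi_i = \rho(s_0-i+1,i)/\mu(i+1)$ accumulated in log space
(overflow-safe for any $N$), with exact zeros for states unreachable after
the susceptible argument hits zero. Two independent routes — the factorial
closed form evaluated via `lgamma`, and a null-space solve of $Q^\top$ —
agree with the recursion to $10^{-10}$ in the tests. The first-order
transition matrix $P$ requires $\Delta t \cdot \max_i(\rho+\mu) \le 1$ and
reports the maximal admissible step when violated.

Gillespie sampling uses inverse-transform exponential waiting times on one
named PCG64 stream per replicate, seeded as `SeedSequence((seed,
replicate))`, so ensembles are bit-reproducible under any execution order.
Ensemble averages sample each jump trajectory by
last-state-carried-forward onto a common grid.

For the N=2000 ensemble-versus-ODE comparison the initial infected count is
20 (1% of N): extinction of the branching phase then has negligible
probability (~$R_0^{-20}$) and the replicate mean is a clean
law-of-large-numbers estimate of the deterministic curve started at
$I(0)=i_0/N$. With a single initial infected, ~12% of runs die out early
and the ensemble mean measures extinction mass rather than agreement.

## Network Monte-Carlo layer

Synchronous discrete-time updates from the step-start configuration:

* infection: a susceptible with $m$ infected living neighbours turns
  infected with probability $1-(1-\beta(1-\delta))^m$ (independent
  per-neighbour transmission; reduces to $\beta(1-\delta)$ for $m=1$).
* recovery: probability $\min(1, \gamma(1+\lambda))$ per step, to R (SIR)
  or back to S (SIS). The alternative $1-e^{-\gamma(1+\lambda)}$ would
  differ only at second order for these rates.
* death: each living node dies with probability $\min(1, d)$ per step.
  Dead nodes drop out of transmission entirely, which is equivalent to
  deleting their edges; the graph object itself is never mutated.
* births: `round(b*n)` newborns per step join a passive, non-transmitting
  pool (the SNES convention, mirroring the mean-field design) and are
  subject to the same death probability. Densities are always normalized
  by the initial node count.

Plain `SIR`/`SIS` variants force $\delta=\lambda=0$; the starred variants
apply both channels. Vaccination acts as a multiplicative transmissibility
reduction for *all* susceptibles — exactly how $\delta$ enters every
analytic formula — not as removal of a $\delta$-fraction of nodes.

All three per-node uniform arrays (infection, recovery, death) are drawn
every step in a fixed order, so two variants run with the same seed consume
identical random streams. This makes replicate coupling well-defined, but
note that synchronous wall-clock coupling does **not** make SIR monotone at
the level of node sets: once trajectories desynchronize, the slower
immunized epidemic can infect a node the plain run happened to miss. The
property that *does* hold, and that the tests assert, is dominance of the
replicate-mean cumulative incidence at every step (a monotone node-set
coupling would require per-edge draws indexed by infection age).

With $d=0.05$ per step the initial population decays with half-life
~14 steps, so SIS runs have a *quasi*-stationary plateau rather than a true
steady state: the plateau forms by ~step 20 and both plain and immunized
models decay at the same demographic rate thereafter. Steady-state metrics
("`I_inf`", "`R_inf`", "`S_inf`") therefore average the final 10% of a
60-step horizon for SIS comparisons; SIR runs use a 100-step horizon, by
which the epidemic is over.

## Synthetic networks

Erdős–Rényi graphs use $G(n, p)$ with $p = \langle k\rangle/(n-1)$;
Barabási–Albert graphs use preferential attachment with $m$ edges per new
node (mean degree $2m(n-m)/n$, slightly below $2m$; reported, not
corrected). The acceptance computation uses $n = 5000$, $\langle k\rangle
= 4$ and 200 replicates per model — large enough that the replicate-mean
peak has a relative standard error of a few percent while the whole
computation stays in the tens of seconds. Real contact networks are
supported only as locally supplied edge lists (whitespace-separated pairs,
`#` comments; self-loops and duplicates dropped with a logged count).

What the generators do *not* emulate: degree–degree correlations,
clustering, community structure, weighted or directed contacts, temporal
rewiring. Tests passing on ER/BA graphs therefore validate the dynamics
and the heterogeneity mechanism ($\langle k^2\rangle/\langle k\rangle$),
not the full structure of empirical contact networks.

## Known limitations

* Stability classification of the equilibria (Lyapunov analysis) is out of
  scope; only existence is computed.
* The CTMC layer has no transient distributions (matrix exponentials) and
  no per-node chain on explicit graphs.
* Mean-field accuracy degrades for strongly heterogeneous graphs at small
  sizes, and the discrete-time simulator deviates from the continuous-time
  models at per-step hazards approaching 1.
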