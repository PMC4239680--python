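"""Reproducible accuracy experiments: heuristic vs. exact reference.

The protocol mirrors the simulation study conditions at a size where the
exhaustive solver is practical: triplet 3-star instances with alphabet
sigma = n/2 and l = n/20 moves per branch (duplications with geometric(0.5)
lengths plus single-gene losses), event counts compared between the 3-star
heuristic and the exact enumerator.  Accuracy is the fraction of instances
with identical counts; Error is (Inf - Opt)/Inf averaged over instances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .median import solve_star
from .oracle import OracleBudget, OracleBudgetError, exact_star_cost
from .simulate import SimulationParams, simulate_star

# study conditions: sigma/n = 1/2 and l/n = 1/20 at the smallest n with a
# whole move per branch
DEFAULT_N = 20
DEFAULT_SIGMA = 10
DEFAULT_L = 1
DEFAULT_REPLICATES = 50


@dataclass
class AccuracyResult:
    replicates: int
    matches: int
    errors: list[float] = field(default_factory=list)
    oracle_failures: int = 0

    @property
    def accuracy(self) -> float:
        return self.matches / self.replicates

    @property
    def mean_error(self) -> float:
        return sum(self.errors) / len(self.errors) if self.errors else 0.0


def replicate_seed(seed: int, index: int) -> int:
    """Derived per-replicate seed, kept below 2^31."""
    return (seed * 1_000_003 + 7919 * index + 13) % (2 ** 31)


def accuracy_experiment(seed: int, replicates: int = DEFAULT_REPLICATES,
                        n: int = DEFAULT_N, sigma: int = DEFAULT_SIGMA,
                        l: int = DEFAULT_L,
                        oracle_budget: OracleBudget | None = None) -> AccuracyResult:
    """Run the heuristic and the exact solver on seeded triplet instances.

    An instance on which the exhaustive solver exceeds its budget counts as
    a non-match (conservative for accuracy) and contributes no error term.
    """
    budget = oracle_budget or OracleBudget(max_genome_len=48,
                                           max_total_len=140,
                                           max_nodes=12_000_000)
    result = AccuracyResult(replicates=replicates, matches=0)
    for i in range(replicates):
        params = SimulationParams(n=n, sigma=sigma, l=l,
                                  model="dup_singleloss",
                                  seed=replicate_seed(seed, i))
        inst, _ = simulate_star(params)
        sol = solve_star(inst)
        try:
            opt = exact_star_cost(inst.A, inst.X, inst.Y, inst.costs,
                                  budget).cost
        except OracleBudgetError:
            result.oracle_failures += 1
            continue
        if abs(sol.cost - opt) < 1e-9:
            result.matches += 1
        if sol.cost > 0:
            result.errors.append((sol.cost - opt) / sol.cost)
    return result
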