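"""Screen a candidate pool for new members of a coevolving network.

Simulates a 12-gene planted network (lambda = 0.6) among 500 background
genes, queries 5 "known" members against a pool holding the 7 remaining
members plus 100 unrelated genes, and applies the selection rule: a
candidate is nominated with empirical p < 0.05 against two or more
queries, or p < 0.01 against one.
"""

from ercov import ERCAnalysis, screen
from ercov.simulate import SimulationSpec, simulate_branch_rates


def main():
    spec = SimulationSpec(n_genes=512, groups=((12, 0.6),), seed=5)
    genes, membership = simulate_branch_rates(spec)
    network = [g for g, k in membership.items() if k == 0]
    background = [g for g, k in membership.items() if k is None]
    queries, hidden = network[:5], network[5:]

    analysis = ERCAnalysis(genes, spec.tree, seed=6, n_null_pairs=10_000)
    report = screen(queries, hidden + background[:100], analysis)

    selected = set(report.selected)
    print(f"queries: {len(queries)} known network genes")
    print(f"pool: {len(report.rows)} candidates "
          f"({len(hidden)} hidden network members + 100 unrelated)")
    print(f"selected: {len(selected)}")
    print(f"  hidden members recovered: "
          f"{sum(c in selected for c in hidden)}/{len(hidden)}")
    print(f"  unrelated genes nominated: "
          f"{sum(c in selected for c in background[:100])}/100")
    print()
    for row in report.rows[:7]:
        flag = "SELECTED" if row.selected else "-"
        print(f"  {row.candidate}  min p={row.min_p:.4f}  "
              f"queries at p<0.05: {row.n_queries_sig}  {flag} "
              f"({row.reason})")
    print()
    print("Hidden network members hit several queries at once; unrelated "
          "genes are nominated only at the rate implied by the rule's "
          "thresholds (~6%).")


if __name__ == "__main__":
    main()
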