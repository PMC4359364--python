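"""CenpC motif and cupin profile scan with architecture calls.

Builds the two profiles from the bundled synthetic seed alignments, scans
a demonstration set (planted CenpC-architecture proteins and matched
negatives), applies the cupin clade test, and writes hit and architecture
tables.
"""

import argparse
from pathlib import Path

import numpy as np

from censcan.motifs import (
    build_profile,
    call_cenpc_architecture,
    scan_profile,
    write_motif_hits_tsv,
)
from censcan.phylogeny import (
    ReferencePanel,
    align_domains,
    build_tree,
    placement_verdict,
)
from censcan.references import (
    load_cenpc_motif_seed,
    load_cupin_seed,
    load_noncenpc_cupin_panel,
)
from censcan.synthetic import divergent_copy, random_protein


def cupin_panel() -> ReferencePanel:
    other = load_noncenpc_cupin_panel()
    outgroup_names = [k for k in other if "outgroup" in k]
    return ReferencePanel(
        host_refs={k: v.replace("-", "") for k, v in load_cupin_seed().items()},
        contaminant_refs={
            k: v for k, v in other.items() if k not in outgroup_names
        },
        outgroup={k: other[k] for k in outgroup_names},
    )


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n", type=int, default=10,
                        help="positives and negatives each")
    parser.add_argument("--outdir", type=Path, default=Path("results/cenpc"))
    args = parser.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(args.seed)
    motif_profile = build_profile(load_cenpc_motif_seed(), name="cenpc_motif")
    cupin_profile = build_profile(load_cupin_seed(), name="cupin")
    panel = cupin_panel()

    hits = []
    arch_rows = []
    for i in range(2 * args.n):
        positive = i < args.n
        pid = f"{'cenpc' if positive else 'negative'}_{i % args.n:02d}"
        host = random_protein(320, rng)
        if positive:
            motif = divergent_copy(motif_profile.consensus, 0.1, rng)
            cupin = divergent_copy(cupin_profile.consensus, 0.1, rng)
            protein = host[:40] + motif + host[40:180] + cupin + host[180:]
        else:
            protein = host
        motif_hit = scan_profile(motif_profile, protein, pid, n_null=999,
                                 seed=args.seed + i)
        cupin_hit = scan_profile(cupin_profile, protein, pid, n_null=999,
                                 seed=args.seed + i)
        hits.extend([motif_hit, cupin_hit])
        verdict = None
        if cupin_hit.pvalue <= 1e-3:
            window = protein[
                cupin_hit.offset: cupin_hit.offset + cupin_profile.width
            ]
            seqs = {"candidate": window, **panel.host_refs,
                    **panel.contaminant_refs, **panel.outgroup}
            tree = build_tree(align_domains(seqs), n_bootstrap=100,
                              seed=args.seed + i)
            verdict = placement_verdict(tree, "candidate", panel)
        arch = call_cenpc_architecture(motif_hit, cupin_hit, verdict)
        arch_rows.append((pid, arch))
        print(f"{pid}: {arch}")

    write_motif_hits_tsv(hits, args.outdir / "motif_hits.tsv")
    with open(args.outdir / "architectures.tsv", "w") as fh:
        fh.write("protein_id\tarchitecture\n")
        for pid, arch in arch_rows:
            fh.write(f"{pid}\t{arch}\n")


if __name__ == "__main__":
    main()
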