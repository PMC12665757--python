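# Literature-derived critical binding motifs for the incretin hormone family.
# Each motif anchors expected residues at 1-based positions in the native
# hormone's own coordinate frame.  frame: n anchors from the N-terminus
# (position 1 = first residue); frame: c anchors from the C-terminus
# (position 1 = last residue).  wildcard = number of mismatches forgiven;
# conservative_credit = partial credit for a same-class substitution.
motifs:
  - name: glp1_critical_nterm        # most critical GLP-1 activation residues, N-terminal half
    frame: n
    positions: {1: H, 3: E, 4: G, 6: F, 7: T, 9: D}
    wildcard: 1
    conservative_credit: 0.5
  - name: glp1_critical_cterm        # critical GLP-1 C-terminal residues
    frame: c
    positions: {9: F, 8: I, 5: L, 1: R}
    wildcard: 1
    conservative_credit: 0.5
  - name: glp1_ortholog_conserved    # conserved across vertebrate orthologs
    frame: n
    positions: {2: A, 3: E, 5: T, 7: T, 13: Y, 18: A, 19: A, 20: K, 21: E, 29: G}
    wildcard: 1
    conservative_credit: 0.5
  - name: glucagon_ortholog_conserved
    frame: n
    positions: {2: S, 3: Q, 5: T, 13: Y, 19: A}
    wildcard: 1
    conservative_credit: 0.5
  - name: gip_ortholog_conserved
    frame: n
    positions: {1: Y, 3: E, 8: S, 11: S, 24: N, 27: L}
    wildcard: 1
    conservative_credit: 0.5
  - name: glp1_paralog_conserved     # conserved across the glucagon-family paralogs
    frame: n
    positions: {1: H, 4: G, 6: F, 9: D, 14: L, 22: F, 23: I, 25: W, 26: L}
    wildcard: 1
    conservative_credit: 0.5
  - name: glucagon_paralog_conserved
    frame: n
    positions: {1: H, 4: G, 6: F, 9: D, 14: L, 15: D, 21: D, 22: F, 23: V, 25: W, 26: L}
    wildcard: 1
    conservative_credit: 0.5
  - name: gip_paralog_conserved
    frame: n
    positions: {4: G, 6: F, 9: D, 15: D, 21: D, 22: F, 23: V, 25: W, 26: L}
    wildcard: 1
    conservative_credit: 0.5
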