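# Default housekeeping gene list (mouse gene symbols).
# Used by the sample filter: cells whose geometric-mean FPKM over these
# genes falls below the threshold are treated as degraded and removed.
# Replace with --housekeeping for other organisms or id namespaces.
Actb
Gapdh
B2m
Hprt
Gusb
Tbp
Ppia
Rpl13a
Ywhaz
Sdha
Hmbs
Pgk1
Ubc
Tfrc
Polr2a
Rplp0
Eef1a1
Rpl27
Hsp90ab1
Psmb4
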