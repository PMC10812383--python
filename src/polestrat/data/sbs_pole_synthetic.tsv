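# Synthetic stand-in for COSMIC v3 SBS10a/10b/14/28 (96-channel probability vectors); see package docs.
Type	SBS10a	SBS10b	SBS14	SBS28
A[C>A]A	0.0250000000	0.0013218391	0.0300000000	0.0013068182
A[C>A]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>A]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>A]T	0.0600000000	0.0013218391	0.1800000000	0.0013068182
C[C>A]A	0.0250000000	0.0013218391	0.0013372093	0.0013068182
C[C>A]C	0.0013855422	0.0013218391	0.0350000000	0.0013068182
C[C>A]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>A]T	0.0800000000	0.0013218391	0.1600000000	0.0013068182
G[C>A]A	0.0150000000	0.0013218391	0.0013372093	0.0013068182
G[C>A]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>A]G	0.0013855422	0.0013218391	0.0200000000	0.0013068182
G[C>A]T	0.0500000000	0.0013218391	0.1200000000	0.0013068182
T[C>A]A	0.0500000000	0.0013218391	0.0400000000	0.0013068182
T[C>A]C	0.0400000000	0.0013218391	0.0013372093	0.0013068182
T[C>A]G	0.0300000000	0.0013218391	0.0013372093	0.0013068182
T[C>A]T	0.4100000000	0.0150000000	0.2200000000	0.0013068182
A[C>G]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>G]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>G]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>G]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>G]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>G]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>G]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>G]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>G]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>G]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>G]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>G]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[C>G]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[C>G]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[C>G]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[C>G]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>T]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>T]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[C>T]G	0.0013855422	0.0600000000	0.0013372093	0.0013068182
A[C>T]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>T]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>T]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[C>T]G	0.0013855422	0.0600000000	0.0500000000	0.0013068182
C[C>T]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>T]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>T]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[C>T]G	0.0200000000	0.1000000000	0.0013372093	0.0013068182
G[C>T]T	0.0013855422	0.0150000000	0.0013372093	0.0013068182
T[C>T]A	0.0013855422	0.0300000000	0.0013372093	0.0013068182
T[C>T]C	0.0013855422	0.0150000000	0.0013372093	0.0013068182
T[C>T]G	0.0300000000	0.5500000000	0.0013372093	0.0013068182
T[C>T]T	0.0500000000	0.0400000000	0.0300000000	0.0013068182
A[T>A]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>A]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>A]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>A]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>A]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>A]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>A]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>A]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>A]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>A]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>A]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>A]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>A]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>A]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>A]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>A]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>C]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>C]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>C]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>C]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>C]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>C]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>C]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>C]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>C]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>C]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>C]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>C]T	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>C]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>C]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>C]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
T[T>C]T	0.0013855422	0.0013218391	0.0013372093	0.0150000000
A[T>G]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>G]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>G]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
A[T>G]T	0.0013855422	0.0013218391	0.0013372093	0.0500000000
C[T>G]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>G]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>G]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
C[T>G]T	0.0013855422	0.0013218391	0.0013372093	0.0700000000
G[T>G]A	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>G]C	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>G]G	0.0013855422	0.0013218391	0.0013372093	0.0013068182
G[T>G]T	0.0013855422	0.0013218391	0.0013372093	0.0400000000
T[T>G]A	0.0013855422	0.0013218391	0.0013372093	0.0200000000
T[T>G]C	0.0013855422	0.0013218391	0.0013372093	0.0400000000
T[T>G]G	0.0013855422	0.0013218391	0.0013372093	0.0300000000
T[T>G]T	0.0013855422	0.0013218391	0.0013372093	0.6200000000
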