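# Four-marker cross Sjk10 (mat1-P, mat2/3D, ade6-dam-E, ura4-D3) x
# Sjk19 (mat1-M, mat2/3D, mrc1D::Nat).  Allele symbols follow the
# octad genotype table: mat1 is scored P/M; ade6 and ura4 are scored
# "+" (prototroph, the Sjk19 allele) / "-" (auxotroph, the Sjk10
# allele); for mrc1 the "+" symbol denotes the mrc1D::Nat cassette
# (nourseothricin-resistant, carried by Sjk19) and "-" the intact,
# drug-sensitive mrc1 allele of Sjk10.
#
# Map positions are centimorgans from the centromere along the named
# arm.  mat1 and ade6 are tightly centromere-linked (placed at 1 cM);
# mrc1 sits on the other arm of chromosome 1 at 47.2 cM so that the
# additive mat1-mrc1 separation is 48.2 cM, the Perkins estimate from
# the 38 PD : 7 NPD : 39 TT cross tally; ura4 has no reported map
# position and is placed mid-arm on chromosome 3.
parent1: Sjk10
parent2: Sjk19
notes: Linear-ascus octad cross segregating mat1, ade6, ura4 and mrc1.
markers:
- name: mat1
  chromosome: chr1
  arm: left
  position_cM: 1.0
  allele_p1: P
  allele_p2: M
- name: ade6
  chromosome: chr2
  arm: left
  position_cM: 1.0
  allele_p1: '-'
  allele_p2: '+'
- name: ura4
  chromosome: chr3
  arm: left
  position_cM: 30.0
  allele_p1: '-'
  allele_p2: '+'
- name: mrc1
  chromosome: chr1
  arm: right
  position_cM: 47.2
  allele_p1: '-'
  allele_p2: '+'
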