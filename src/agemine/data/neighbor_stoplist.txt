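# Words too generic to anchor a gene symbol: they occur in the full names of
# many unrelated genes, so their presence in a sentence says nothing about
# which gene an ambiguous symbol refers to.  One word per line; lines starting
# with '#' are comments.  Matching is lowercase.
receptor
tyrosine
kinase
antigen
mutant
protein
gene
factor
family
member
domain
subunit
chain
type
alpha
beta
gamma
delta
like
associated
containing
binding
homolog
precursor
related
regulator
regulatory
activated
dependent
induced
linked
putative
open
reading
frame
candidate
region
pseudogene
transcript
variant
isoform
complex
component
enzyme
molecule
cell
surface
human
small
large
heavy
light
group
class
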