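species,genome_size_mbp,rate_low,rate_high,basis,unit
Human,3080,1e-8,2.5e-8,per_base,per_generation
Human,3080,1.75e2,1.75e2,per_genome,per_generation
Human,3080,5e-11,6e-2,per_base,per_cell_division
Human,3080,1.6e-1,1.6e-1,per_genome,per_cell_division
Human (Y chromosome),58,3e-8,3e-8,per_base,per_generation
"Human, chimpanzee",3080,3,3,per_genome,per_generation
D. melanogaster,120,4.65e-9,6.2e-8,per_base,per_generation
D. melanogaster,120,9.9e-1,1.2,per_genome,per_generation
Drosophila spp.,120,7e-2,7e-2,per_genome,per_generation
D. melanogaster,120,1.3e-10,3.4e-10,per_base,per_cell_division
"Quail, chicken",1050,4.9e-1,4.9e-1,per_genome,per_generation
"Sheep, cow",2870,9e-1,9e-1,per_genome,per_generation
Old World Monkey,,1.9,1.9,per_genome,per_generation
"Mouse, rat",2640,9.1e-1,9.1e-1,per_genome,per_generation
Mouse,2640,1.8e-10,1.8e-10,per_base,per_cell_division
Mouse,2640,1.1e-8,1.1e-8,per_base,per_generation
S. cerevisiae,12.1,3.3e-10,3.3e-10,per_base,per_generation
S. cerevisiae,12.1,3.3e-10,3.3e-10,per_base,per_cell_division
Average mammalian,,2.2e-9,2.2e-9,per_base,per_genome_year
Mammalian upper bound,,2.61e-9,2.61e-9,per_base,per_genome_year
C. elegans,100,8.4e-9,2.1e-8,per_base,per_generation
C. elegans,100,2.9,2.9,per_genome,per_generation
A. thaliana,157,7.1e-9,7.1e-9,per_base,per_generation
A. thaliana,157,6.5e-9,6.5e-9,per_base,per_generation
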