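taxon,score
Drunella,25
Epeorus,22
Rhithrogena,22
Cinygmula,18
Yoraperla,20
Megarcys,18
Zapada,16
Doroneuria,16
Glossosoma,15
Neophylax,14
Rhyacophila,10
Micrasema,9
Brachycentrus,8
Sweltsa,8
Heterlimnius,7
Cleptelmis,6
Narpus,6
Optioservus,5
Baetis,2
Hydropsyche,2
Simulium,1
Sphaerium,1
Chironomidae,0
Oligochaeta,0
Physa,0
Ostracoda,0
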