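>BCT_synthetic synthetic stand-in reference for a butyryl-CoA transferase marker protein (not a real database sequence)
MLAMLVSLHNPEDERGNFRDVIQTDSLEQGPLRDIALLSSLMGRAQAVPIALPSSEELEE
ASTKIVLQERQLKPEKEGGVYFEDASGHQGYGVNMGDSVIEVETSHDLRTDGQKLQRKIY
WHLRLVQDLTPGAVQGNGKSIPSQIANLDLKIAVNGPLFLFDAFLGNGKAELHNDEEQAR
TTWMCGGDQEIRDPLDKIAGQTVTQFIGESHQHQMGPALVAYGDRGGISPLAIISLHLKL
YRGYLVIHVSSTFELTKFILEALGPEWVTALVKLWCSCSEGATEGLKLCSWYYDWRIDWF
YNNTVARSAEGLDAHRETAHPIRGIGGHYNIAKMHNIAWYIDLQYGIQHRVYDVARNPAL
GFILMPSIDEYKASLRTEPNGVSTLVNSVSEGQMETRRVVYAGKLRDLAEDGIPESKTCW
ATTAEAVFVRNFSDDRVGADITDTTANQGN
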