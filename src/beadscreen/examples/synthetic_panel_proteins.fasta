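>synthetic_high_pI_example_1 synthetic sequence (not a real protein); lysine/arginine-rich, high pI, models a positively charged target like a cytokine at neutral pH
MKRLKKAVRSGLKHKTRLAKAVKGGRWSKHLNKAIARKGGLKQRVSKLAKHGRTKAVLGG
KRSLHKAVTKGGRLAKYVNKHARSGGKLTKRVAKWGG
>synthetic_high_pI_example_2 synthetic sequence (not a real protein); histidine/arginine-rich basic chain
MARHGKHLVRSGGKTHRLAKAVHGGRWSRHLNKAIARHGGLKQRVSHLAKHGRTKAVLGG
HRSLHKAVTRGG
>synthetic_low_pI_example_1 synthetic sequence (not a real protein); aspartate/glutamate-rich, low pI, models an acidic specificity-control protein
MDELDEAVESGLDHETELAEAVDGGEWSDHLNEAIAEDGGLEQDVSELAEHGETDAVLGG
DESLHEAVTEGGELAEYVNEHAESGG
>synthetic_low_pI_example_2 synthetic sequence (not a real protein); acidic chain with aromatic content
MAEYDGEWLVDSGGETHELAEAVDGGYWSEDLNEAIAEDGGLEQYVSDLAEGGETDAVWG
G
>synthetic_neutral_example_1 synthetic sequence (not a real protein); balanced charge composition near neutral pI
MKDLAEAVRSGLDHKTELAKAVDGGRWSEHLNKAIAEDGGLKQRVSDLAEHGRTDAVLGG
KESLHDAVTRGG
>synthetic_neutral_example_2 synthetic sequence (not a real protein); mixed composition with cysteine and tyrosine
MACDYGKWLVRSGGETHCLAKAVDGGYWSEDLNKAIACRGGLEQYVSDLAKGGCTDAVWG
GYH
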