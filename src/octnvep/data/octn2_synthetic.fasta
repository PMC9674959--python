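>OCTN2_SYNTHETIC_L557 synthetic stand-in, canonical OCTN2 length (557 aa)
SKDRKKNDMSYHYRGKEIEGQSYREYNSQHQNDERHKNPWCRHAGIIVILVFYVLIIICS
CLLLVVDDMNSRMDRRYEHEHAEWRQKPKPKSSRKRWSKEGKSKHDREDWAYHNAQKWHN
TGNETEERCPWWWHPRQHDQDEGNHAARHQVNYCNKTFPFIVLFLMIVVSILLFSIIENR
NWPGNRGELDRACVVIVIVMIIILVIVVIVIVCEHDHLVFITLVIFVNVFILIVIVVFYP
RNHYHKEEYTPPHLLILCIIFFVFIVLLILLVVISDYHAQQHYRSRAILVIFVIFMLLLI
LVIIMSCFRDVHPNYRMWYSRDAIIFLFYVIIIIAIMWVLAMVYSCQSDEGRYGICLLFV
LCLVCCAVVVLCVIVNKRTHHWKGRPTNTIVLCLLVLVVVIGIVMILVIVIKRVVVCIAI
AIVLGCMLWVVVIVHHQMDYKLEVENKRRLVCLAYLVWCLFIMIIVCIVAYEDNWTRGEH
NCVIVLLVAVVITVISMVIVCFVVHPDFNPSEEKNHHDEAANAEKANNKKAYMHPRWPED
QQYDHYEWHNEERSDKA
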