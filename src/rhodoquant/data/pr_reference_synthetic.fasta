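>PR_ref_synthetic synthetic proteorhodopsin-like coordinate template (D97/T101/L105/E108)
TVLQTSGISCADYSQYASKMARLHVMRTFDHMVVIQATTYGNANPAWVARMRFEAWNVLT
WSVNLELDAVATSTSRSDLSHANLTVWVFGWSAVRSDLIATAATLARETAAHAVPIDILV
DNGIVGWVMAPGLLIHEGVVNLIGVFTTYPLASWLGMYAGTCISVGFLWATRFVMTIFDQ
FPFLVYYVGGLVLLVMGRLAALPVIKKPVEYRRLDEPAEGLTRTADQVSRALPCFNVTLA
RLDHKLNLL
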